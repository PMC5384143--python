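import numpy as np
import pytest
from scipy.optimize import nnls as scipy_nnls

from dbspectra.dbsi import (
    DBSIConfig,
    estimate_fiber_direction,
    fit_dbsi,
    fit_isotropic_spectrum,
    partition_spectrum,
)
from dbspectra.dti import FitError
from dbspectra.signal_model import (
    B_CONVERSION,
    IsotropicSpectrum,
    add_rician_noise,
    predict_signal,
)

from conftest import Z, make_voxel, random_fiber_voxel


class TestConfig:
    def test_default_grid_is_31_points(self, dbsi_config):
        grid = dbsi_config.grid
        assert grid.size == 31
        assert grid[0] == 0.0 and grid[-1] == 3.0
        assert np.allclose(np.diff(grid), 0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"restricted_threshold": 3.5},
            {"grid_step": 0.07},
            {"regularization_weight": -1.0},
            {"lambda_par_bounds": (3.0, 0.5)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DBSIConfig(**kwargs)


class TestFiberDirection:
    def test_axis_aligned_fiber(self, scheme):
        x = np.array([1.0, 0.0, 0.0])
        truth = make_voxel(x, 1.8, 0.2, 1.0)
        direction, flag = estimate_fiber_direction(predict_signal(truth, scheme), scheme)
        angle = np.degrees(np.arccos(min(abs(direction @ x), 1.0)))
        assert angle < 0.5
        assert not flag

    def test_isotropic_voxel_tie_break(self, scheme):
        truth = make_voxel(Z, 1.0, 1.0, 0.0, iso_ds=(2.0,), iso_ws=(1.0,))
        direction, flag = estimate_fiber_direction(predict_signal(truth, scheme), scheme)
        assert flag
        assert np.array_equal(direction, Z)

    def test_oblique_fiber_with_isotropic_contamination(self, scheme):
        d45 = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)
        truth = make_voxel(d45, 1.8, 0.2, 0.8, iso_ds=(1.0,), iso_ws=(0.2,))
        direction, flag = estimate_fiber_direction(predict_signal(truth, scheme), scheme)
        angle = np.degrees(np.arccos(min(abs(direction @ d45), 1.0)))
        assert angle < 2.0
        assert not flag


class TestSpectrumInversion:
    def test_fiber_only_self_consistency(self, scheme, dbsi_config):
        truth = make_voxel(Z, 1.79, 0.17, 1.0)
        fw, spectrum, _ = fit_isotropic_spectrum(
            predict_signal(truth, scheme), scheme, Z, 1.79, 0.17, dbsi_config
        )
        total = fw + spectrum.total_weight
        assert fw / total > 0.99
        assert spectrum.total_weight / total < 0.01

    def test_on_grid_mixture_exact_at_zero_ridge(self, scheme):
        config = DBSIConfig(regularization_weight=0.0)
        truth = make_voxel(Z, 1.79, 0.17, 0.0, iso_ds=(0.2, 2.0), iso_ws=(0.4, 0.6))
        signal = predict_signal(truth, scheme)
        fw, spectrum, residual = fit_isotropic_spectrum(
            signal, scheme, Z, 1.79, 0.17, config
        )
        expected = np.zeros(31)
        expected[2] = 0.4   # D = 0.2
        expected[20] = 0.6  # D = 2.0
        assert np.abs(spectrum.weights - expected).max() < 1e-6
        assert fw < 1e-6
        assert residual < 1e-9

    def test_matches_scipy_active_set_oracle(self, scheme):
        """Own Lawson-Hanson solver vs scipy's NNLS on the same design.

        Mixtures pair a restricted pool (cells) with a fast pool
        (edema/CSF), the configuration the spectrum is built to
        separate; on such designs the nonnegative solution is unique,
        so weight-level agreement is well defined.
        """
        config = DBSIConfig(regularization_weight=0.0)
        rng = np.random.default_rng(23)
        b = scheme.bvalues * B_CONVERSION
        for _ in range(20):
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            lpar, lperp = rng.uniform(1.0, 2.5), rng.uniform(0.05, 0.5)
            picks = np.array([rng.integers(0, 4), rng.integers(12, 31)])
            ws = rng.dirichlet([1, 1]) * rng.uniform(0.2, 0.8)
            truth = make_voxel(
                v, lpar, lperp, 1.0 - ws.sum(),
                iso_ds=config.grid[picks], iso_ws=ws,
            )
            signal = predict_signal(truth, scheme)
            fw, spectrum, _ = fit_isotropic_spectrum(signal, scheme, v, lpar, lperp, config)
            cos2 = (scheme.directions @ v) ** 2
            fiber_col = np.exp(-b * lperp - b * (lpar - lperp) * cos2)
            A = np.column_stack([fiber_col, np.exp(-np.outer(b, config.grid))])
            expected, _ = scipy_nnls(A, signal)
            mine = np.concatenate([[fw], spectrum.weights])
            assert np.abs(mine - expected).max() < 1e-6

    def test_noisy_fiber_weight_bias_small(self, scheme, dbsi_config):
        truth = make_voxel(Z, 1.79, 0.17, 0.85, iso_ds=(0.15, 1.5), iso_ws=(0.01, 0.14))
        clean = predict_signal(truth, scheme)
        fractions = []
        for i in range(200):
            noisy = add_rician_noise(clean, snr=30.0, seed=3000 + i)
            fw, spectrum, _ = fit_isotropic_spectrum(
                noisy, scheme, Z, 1.79, 0.17, dbsi_config
            )
            fractions.append(fw / (fw + spectrum.total_weight))
        assert abs(np.mean(fractions) - 0.85) < 0.05

    def test_all_zero_signal_rejected(self, scheme, dbsi_config):
        with pytest.raises(FitError):
            fit_isotropic_spectrum(
                np.zeros(scheme.n_volumes), scheme, Z, 1.79, 0.17, dbsi_config
            )

    def test_out_of_bounds_diffusivities_rejected(self, scheme, dbsi_config):
        signal = np.ones(scheme.n_volumes)
        with pytest.raises(ValueError):
            fit_isotropic_spectrum(signal, scheme, Z, 4.0, 0.17, dbsi_config)


class TestPartition:
    def test_all_restricted(self):
        spec = IsotropicSpectrum([0.2], [1.0])
        assert partition_spectrum(spec) == (1.0, 0.0)

    def test_boundary_inclusive(self):
        spec = IsotropicSpectrum([0.3], [1.0])
        assert partition_spectrum(spec) == (1.0, 0.0)

    def test_split(self):
        spec = IsotropicSpectrum([0.1, 1.0], [0.3, 0.7])
        r, nr = partition_spectrum(spec)
        assert r == pytest.approx(0.3)
        assert nr == pytest.approx(0.7)

    def test_mass_conserved(self):
        rng = np.random.default_rng(1)
        grid = np.linspace(0, 3, 31)
        for _ in range(20):
            w = rng.random(31)
            spec = IsotropicSpectrum(grid, w)
            r, nr = partition_spectrum(spec)
            assert abs((r + nr) - w.sum()) < 1e-12


class TestFullInversion:
    def test_baseline_like_voxel_recovery(self, scheme):
        truth = make_voxel(Z, 1.79, 0.17, 0.85, iso_ds=(0.15, 1.5), iso_ws=(0.01, 0.14))
        fit = fit_dbsi(predict_signal(truth, scheme), scheme)
        assert abs(fit.fiber_fraction - 0.85) < 0.03
        assert abs(fit.lambda_par - 1.79) < 0.05

    def test_pure_csf_voxel(self, scheme):
        truth = make_voxel(Z, 1.0, 1.0, 0.0, iso_ds=(3.0,), iso_ws=(1.0,))
        fit = fit_dbsi(predict_signal(truth, scheme), scheme)
        assert fit.fiber_fraction < 0.05
        assert fit.near_isotropic

    def test_fractions_sum_to_one(self, scheme):
        rng = np.random.default_rng(77)
        for _ in range(10):
            truth = random_fiber_voxel(rng)
            fit = fit_dbsi(predict_signal(truth, scheme), scheme)
            total = fit.fiber_fraction + fit.restricted_fraction + fit.nonrestricted_fraction
            assert abs(total - 1.0) < 1e-6

    def test_deterministic(self, scheme):
        truth = make_voxel(Z, 1.6, 0.3, 0.7, iso_ds=(0.15, 1.5), iso_ws=(0.1, 0.2))
        signal = add_rician_noise(predict_signal(truth, scheme), 30.0, seed=9)
        a = fit_dbsi(signal, scheme)
        b = fit_dbsi(signal, scheme)
        assert a.fiber_fraction == b.fiber_fraction
        assert a.lambda_par == b.lambda_par
        assert np.array_equal(a.spectrum.weights, b.spectrum.weights)

    def test_confound_separation_single_point(self, scheme):
        """At heavy isotropic load the paired DTI fit is dragged down
        while the spectral fit stays near the fiber's true λ∥."""
        from dbspectra.dti import fit_dti

        truth = make_voxel(Z, 1.82, 0.2, 0.83, iso_ds=(0.15, 1.5), iso_ws=(0.08, 0.09))
        signal = predict_signal(truth, scheme)
        dbsi = fit_dbsi(signal, scheme)
        dti = fit_dti(signal, scheme)
        assert abs(dbsi.lambda_par - 1.82) < 0.1
        assert dti.lambda_par < 1.82 - 0.15
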