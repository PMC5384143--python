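import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dbspectra.acquisition import GradientScheme
from dbspectra.signal_model import (
    AnisotropicComponent,
    B_CONVERSION,
    IsotropicSpectrum,
    VoxelTruth,
    add_rician_noise,
    predict_signal,
    rician_bias_correct,
)

from conftest import Z, make_voxel, random_fiber_voxel


def brute_force_signal(truth, scheme):
    """Independent oracle: full 3x3 tensor per compartment, summed."""
    b = scheme.bvalues * B_CONVERSION
    g = scheme.directions
    n = truth.aniso.principal_direction
    D_fiber = truth.aniso.lambda_perp * np.eye(3) + (
        truth.aniso.lambda_par - truth.aniso.lambda_perp
    ) * np.outer(n, n)
    out = np.zeros(scheme.n_volumes)
    for k in range(scheme.n_volumes):
        out[k] = truth.aniso.fraction * np.exp(-b[k] * g[k] @ D_fiber @ g[k])
        for D, w in zip(truth.iso.grid, truth.iso.weights):
            out[k] += w * np.exp(-b[k] * D)
    return truth.s0 * out


class TestPredictSignal:
    def test_pure_isotropic_closed_form(self, scheme):
        truth = make_voxel(Z, 1.0, 1.0, 0.0, iso_ds=(3.0,), iso_ws=(1.0,))
        custom = GradientScheme([[0, 0, 0], [1.0, 0, 0]], [0.0, 1000.0])
        s = predict_signal(truth, custom)
        assert s[0] == pytest.approx(1.0)
        assert s[1] == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_fiber_only_perpendicular_closed_form(self):
        truth = make_voxel(Z, 1.79, 0.17, 1.0)
        custom = GradientScheme([[1.0, 0, 0]], [1000.0])  # gradient ⊥ fiber
        s = predict_signal(truth, custom)
        assert s[0] == pytest.approx(np.exp(-0.17), rel=1e-12)

    def test_b0_returns_s0(self, scheme):
        truth = make_voxel(Z, 1.8, 0.2, 0.7, iso_ds=(0.15, 1.5), iso_ws=(0.1, 0.2), s0=2.5)
        assert predict_signal(truth, scheme)[0] == pytest.approx(2.5, rel=1e-12)

    def test_matches_per_compartment_tensor_oracle(self, scheme):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            truth = random_fiber_voxel(rng)
            delta = np.abs(
                predict_signal(truth, scheme) - brute_force_signal(truth, scheme)
            ).max()
            worst = max(worst, delta)
        assert worst < 1e-12

    def test_signal_monotone_in_b_along_fixed_direction(self):
        rng = np.random.default_rng(5)
        g = np.array([0.6, 0.0, 0.8])
        bvals = np.linspace(0.0, 2200.0, 12)
        sch = GradientScheme(np.tile(g, (12, 1)), bvals)
        for _ in range(20):
            truth = random_fiber_voxel(rng)
            s = predict_signal(truth, sch)
            assert np.all(np.diff(s) <= 1e-15)

    def test_rotation_equivariance(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(10):
            truth = random_fiber_voxel(rng)
            R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
            rotated_truth = VoxelTruth(
                AnisotropicComponent(
                    R @ truth.aniso.principal_direction,
                    truth.aniso.lambda_par,
                    truth.aniso.lambda_perp,
                    truth.aniso.fraction,
                ),
                truth.iso,
                truth.s0,
            )
            rotated_scheme = GradientScheme(scheme.directions @ R.T, scheme.bvalues)
            s1 = predict_signal(truth, scheme)
            s2 = predict_signal(rotated_truth, rotated_scheme)
            assert np.abs(s1 - s2).max() < 1e-9


class TestVoxelTruthInvariants:
    def test_unnormalized_fractions_rejected(self):
        with pytest.raises(ValueError):
            make_voxel(Z, 1.8, 0.2, 0.7, iso_ds=(1.5,), iso_ws=(0.5,))

    def test_lambda_ordering_enforced(self):
        with pytest.raises(ValueError):
            AnisotropicComponent(Z, 0.2, 1.8, 1.0)

    def test_spectrum_grid_must_increase(self):
        with pytest.raises(ValueError):
            IsotropicSpectrum([1.0, 0.5], [0.5, 0.5])


class TestRicianNoise:
    def test_infinite_snr_limit(self, scheme):
        truth = make_voxel(Z, 1.8, 0.2, 1.0)
        clean = predict_signal(truth, scheme)
        noisy = add_rician_noise(clean, snr=1e12, seed=0)
        assert np.abs(noisy - clean).max() < 1e-9

    def test_rayleigh_mean_on_zero_signal(self):
        sigma = 1.0 / 20.0
        n = 100_000
        out = add_rician_noise(np.zeros(n), snr=20.0, seed=1, s0=1.0)
        expected = sigma * np.sqrt(np.pi / 2.0)
        se = sigma * np.sqrt((4 - np.pi) / 2.0) / np.sqrt(n)
        assert abs(out.mean() - expected) < 3 * se

    def test_seed_determinism(self, scheme):
        clean = predict_signal(make_voxel(Z, 1.8, 0.2, 1.0), scheme)
        a = add_rician_noise(clean, 30.0, seed=42)
        b = add_rician_noise(clean, 30.0, seed=42)
        assert np.array_equal(a, b)
        c = add_rician_noise(clean, 30.0, seed=43)
        assert not np.array_equal(a, c)

    def test_invalid_snr_rejected(self):
        with pytest.raises(ValueError):
            add_rician_noise(np.ones(3), snr=0.0, seed=0)


class TestRicianBiasCorrection:
    def test_censored_mode_nonnegative_and_exact_above_floor(self):
        s = np.array([0.0, 0.02, 1.0])
        out = rician_bias_correct(s, sigma=0.03, mode="censored")
        assert np.all(out >= 0)
        assert out[2] == pytest.approx(np.sqrt(1.0 - 2 * 0.03**2))

    def test_signed_mode_reduces_rayleigh_floor_bias(self):
        rng_out = add_rician_noise(np.zeros(50_000), snr=30.0, seed=3, s0=1.0)
        corrected = rician_bias_correct(rng_out, sigma=1 / 30.0, mode="signed")
        # raw Rayleigh mean is ~1.25 sigma; signed correction is near zero-mean
        assert abs(corrected.mean()) < 0.3 * rng_out.mean()

    def test_invalid_args_rejected(self):
        with pytest.raises(ValueError):
            rician_bias_correct(np.ones(3), sigma=-1.0)
        with pytest.raises(ValueError):
            rician_bias_correct(np.ones(3), sigma=0.1, mode="bogus")
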