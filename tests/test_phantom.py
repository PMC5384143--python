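import numpy as np
import pandas as pd
import pytest

from dbspectra.phantom import (
    CohortConfig,
    HistologyCoupling,
    NerveTimepointConfig,
    StainCoupling,
    TIMEPOINT_PRESETS,
    make_cohort,
    make_histology,
    make_nerve,
)
from dbspectra.signal_model import predict_signal
from dbspectra.stats import linear_regression

VOXEL_VOLUME = 0.117 * 0.117 * 0.8


class TestMakeNerve:
    def test_baseline_disc_is_seven_voxels(self, scheme):
        ds = make_nerve(TIMEPOINT_PRESETS["baseline"], scheme=scheme, seed=0)
        assert int(ds.nerve_mask.sum()) == round(0.08 / VOXEL_VOLUME) == 7

    def test_swollen_nerve_has_more_voxels(self, scheme):
        base = make_nerve(TIMEPOINT_PRESETS["baseline"], scheme=scheme, seed=0)
        t1 = make_nerve(TIMEPOINT_PRESETS["time1"], scheme=scheme, seed=0)
        t2 = make_nerve(TIMEPOINT_PRESETS["time2"], scheme=scheme, seed=0)
        assert t1.nerve_mask.sum() > base.nerve_mask.sum()
        assert t2.nerve_mask.sum() > t1.nerve_mask.sum()

    def test_seed_determinism_bit_identical(self, scheme):
        a = make_nerve(TIMEPOINT_PRESETS["time1"], scheme=scheme, seed=5)
        b = make_nerve(TIMEPOINT_PRESETS["time1"], scheme=scheme, seed=5)
        assert np.array_equal(a.dwi, b.dwi)
        assert np.array_equal(a.nerve_mask, b.nerve_mask)
        for k in a.truth_maps:
            assert np.array_equal(a.truth_maps[k], b.truth_maps[k], equal_nan=True)

    def test_truth_maps_regenerate_noise_free_signal(self, scheme):
        ds = make_nerve(TIMEPOINT_PRESETS["time2"], scheme=scheme, seed=2)
        regenerated = ds.noise_free
        for (i, j), truth in ds.voxel_truths.items():
            delta = np.abs(
                regenerated[i, j, 0, :] - predict_signal(truth, ds.scheme)
            ).max()
            assert delta < 1e-12

    def test_center_roi_inside_nerve(self, scheme):
        ds = make_nerve(TIMEPOINT_PRESETS["baseline"], scheme=scheme, seed=1)
        assert ds.center_roi_mask.any()
        assert not (ds.center_roi_mask & ~ds.nerve_mask).any()

    def test_subvoxel_volume_rejected(self, scheme):
        tiny = NerveTimepointConfig(
            mean_lambda_par=1.79, mean_lambda_perp=0.17,
            mean_fiber_fraction=0.97, mean_restricted_fraction=0.01,
            mean_nonrestricted_fraction=0.02, nerve_volume=0.001,
        )
        with pytest.raises(ValueError):
            make_nerve(tiny, scheme=scheme, seed=0)

    def test_preset_fractions_normalized(self):
        for preset in TIMEPOINT_PRESETS.values():
            total = (preset.mean_fiber_fraction
                     + preset.mean_restricted_fraction
                     + preset.mean_nonrestricted_fraction)
            assert abs(total - 1.0) < 1e-6


class TestMakeCohort:
    def test_dataset_count(self, scheme):
        datasets, table = make_cohort(CohortConfig(n_mice=8), 0, scheme=scheme)
        assert len(datasets) == 48
        assert len(table) == 48

    def test_axon_volume_bookkeeping_exact(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=3), 1, scheme=scheme)
        for (_, _), grp in table.groupby(["mouse", "eye"]):
            base = grp[grp.timepoint == "baseline"].iloc[0]
            t1 = grp[grp.timepoint == "time1"].iloc[0]
            t2 = grp[grp.timepoint == "time2"].iloc[0]
            if t1.converting:
                assert t1.axon_volume_true == pytest.approx(
                    base.axon_volume_true * 0.84, abs=1e-9
                )
                assert t2.axon_volume_true == pytest.approx(
                    base.axon_volume_true * 0.83, abs=1e-9
                )
            else:
                assert t1.axon_volume_true == pytest.approx(
                    base.axon_volume_true, abs=1e-12
                )

    def test_visual_acuity_thresholds(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=8), 2, scheme=scheme)
        baseline = table[table.timepoint == "baseline"]
        assert (baseline.va > 0.25).all()
        onset = table[(table.timepoint == "time1") & table.converting]
        assert (onset.va <= 0.25).all()

    def test_single_nonconverting_eye2(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=8), 3, scheme=scheme)
        nonconv = table[~table.converting]
        assert nonconv.eye.unique().tolist() == [2]
        assert nonconv.mouse.nunique() == 1
        # stays at baseline truth at all timepoints
        assert nonconv.fiber_fraction_true.nunique() == 1

    def test_subseed_splitting_rule(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=2), 7, scheme=scheme)
        assert table.seed.tolist() == [7 * 10_000 + i for i in range(len(table))]

    def test_master_seed_determinism(self, scheme):
        a_ds, a_tab = make_cohort(CohortConfig(n_mice=2), 5, scheme=scheme)
        b_ds, b_tab = make_cohort(CohortConfig(n_mice=2), 5, scheme=scheme)
        pd.testing.assert_frame_equal(a_tab, b_tab)
        assert all(
            np.array_equal(x.dwi, y.dwi) for x, y in zip(a_ds, b_ds)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(snr=-1.0)
        with pytest.raises(ValueError):
            CohortConfig(axon_loss_time1=1.5)


class TestHistology:
    def test_identity_coupling_zero_noise(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=4), 0, scheme=scheme)
        t2 = table[table.timepoint == "time2"].reset_index(drop=True)
        identity = HistologyCoupling(
            smi31=StainCoupling("lambda_par", 1.0, 0.0, 0.0, 0.0, np.inf),
            mbp=StainCoupling("lambda_perp", 1.0, 0.0, 0.0, 0.0, np.inf),
            smi312=StainCoupling("fiber_fraction", 1.0, 0.0, 0.0, 0.0, np.inf),
            dapi=StainCoupling("restricted_fraction", 1.0, 0.0, 0.0, 0.0, np.inf),
        )
        histo = make_histology(t2, identity, seed=0)
        assert np.allclose(histo.smi31, t2.lambda_par_true)
        assert np.allclose(histo.smi312, t2.fiber_fraction_true)

    def test_default_coupling_slope_recovery(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=8), 4, scheme=scheme)
        t2 = table[table.timepoint == "time2"].reset_index(drop=True)
        coupling = HistologyCoupling()
        histo = make_histology(t2, coupling, seed=4)
        res = linear_regression(t2.fiber_fraction_true, histo.smi312)
        assert abs(res.slope - coupling.smi312.slope) < 2 * res.slope_se

    def test_negative_mbp_coupling_sign(self, scheme):
        _, table = make_cohort(CohortConfig(n_mice=8), 6, scheme=scheme)
        t2 = table[table.timepoint == "time2"].reset_index(drop=True)
        negatives = 0
        for s in range(100):
            histo = make_histology(t2, HistologyCoupling(), seed=s)
            res = linear_regression(t2.lambda_perp_true, histo.mbp)
            negatives += res.slope < 0
        assert negatives >= 95
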