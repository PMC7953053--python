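"""Test-retest metrics: Dice, wCV, ICC(3,1), ROI paired comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bhcvr.pipeline import analyze_session
from bhcvr.repeatability import (
    dice,
    icc31,
    icc_summary,
    roi_paired_compare,
    wcv_and_diff,
)
from bhcvr.synthetic import NoiseModel, generate_phantom, simulate_retest


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4), bool)
        m[:2] = True
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:3], b[5:] = True, True
        assert dice(a, b) == 0.0

    def test_hand_count(self):
        a = np.array([1, 1, 1, 0, 0], bool)
        b = np.array([1, 1, 0, 1, 0], bool)
        assert dice(a, b) == pytest.approx(2 * 2 / 6)

    def test_both_empty_flagged(self):
        assert np.isnan(dice(np.zeros(5, bool), np.zeros(5, bool)))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros(4, bool), np.zeros(5, bool))

    @given(hnp.arrays(bool, 30), hnp.arrays(bool, 30))
    @settings(max_examples=50, deadline=None)
    def test_symmetric(self, a, b):
        d1, d2 = dice(a, b), dice(b, a)
        assert (np.isnan(d1) and np.isnan(d2)) or d1 == d2


class TestWCV:
    def test_identical_maps_zero(self):
        m = np.abs(np.random.default_rng(0).random((3, 3))) + 1
        gm = np.ones((3, 3), bool)
        out = wcv_and_diff(m, m, gm)
        assert out.gm_mean_diff == 0.0
        assert out.gm_mean_wcv == 0.0

    def test_pair_hand_value(self):
        out = wcv_and_diff(np.array([1.0]), np.array([3.0]), np.array([True]))
        assert out.wcv_map[0] == pytest.approx(np.sqrt(2) / 2)
        assert out.diff_map[0] == pytest.approx(2.0)

    @given(c=st.floats(0.1, 50.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariant(self, c):
        a = np.array([1.0, 2.0, 0.5])
        b = np.array([1.5, 1.0, 0.75])
        gm = np.ones(3, bool)
        base = wcv_and_diff(a, b, gm)
        scaled = wcv_and_diff(c * a, c * b, gm)
        assert scaled.wcv_map == pytest.approx(base.wcv_map)

    def test_nonpositive_mean_excluded(self):
        out = wcv_and_diff(np.array([1.0, -2.0]), np.array([3.0, 1.0]),
                           np.array([True, True]))
        assert out.wcv_valid.tolist() == [True, False]

    def test_empty_gm_rejected(self):
        with pytest.raises(ValueError):
            wcv_and_diff(np.ones(3), np.ones(3), np.zeros(3, bool))


class TestICC31:
    def test_session_offset_gives_perfect_consistency(self):
        v = np.array([[1.0, 2.0], [2.0, 3.0], [3.0, 4.0], [4.0, 5.0]])
        assert icc31(v) == pytest.approx(1.0)

    def test_null_data_near_zero(self):
        v = np.random.default_rng(0).standard_normal((200, 2))
        assert abs(icc31(v)) < 0.15

    def test_matches_independent_anova_oracle(self):
        """Cross-check against pingouin's ICC(C,1) on random 6x2 tables."""
        import pingouin as pg

        for seed in range(5):
            tab = np.random.default_rng(seed).standard_normal((6, 2))
            long = pd.DataFrame({
                "subj": np.repeat(np.arange(6), 2),
                "sess": np.tile([0, 1], 6),
                "y": tab.ravel(),
            })
            res = pg.intraclass_corr(long, "subj", "sess", "y")
            oracle = float(res.loc[res["Type"] == "ICC(C,1)", "ICC"].iloc[0])
            assert icc31(tab) == pytest.approx(oracle, abs=1e-9)

    @given(a=st.floats(0.5, 3.0), b=st.floats(-5.0, 5.0))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariant(self, a, b):
        v = np.random.default_rng(3).standard_normal((8, 2)) + np.arange(8)[:, None]
        assert icc31(a * v + b) == pytest.approx(icc31(v), abs=1e-9)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal((6, 2, 10))
        vec = icc31(v)
        for j in range(10):
            assert vec[j] == pytest.approx(icc31(v[:, :, j]), abs=1e-12)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc31(np.ones((2, 2)))

    def test_degenerate_all_constant_flagged(self):
        assert np.isnan(icc31(np.ones((5, 2))))


class TestICCSummary:
    def test_all_ones(self):
        out = icc_summary(np.ones(100), np.ones(100, bool))
        assert all(v == 100.0 for v in out.values())

    def test_all_zero(self):
        out = icc_summary(np.zeros(100), np.ones(100, bool))
        assert all(v == 0.0 for v in out.values())

    def test_uniform_tail_fractions(self):
        icc = np.random.default_rng(0).uniform(0, 1, 10_000)
        out = icc_summary(icc, np.ones(10_000, bool))
        assert out[0.4] == pytest.approx(60.0, abs=2.0)
        assert out[0.6] == pytest.approx(40.0, abs=2.0)
        assert out[0.8] == pytest.approx(20.0, abs=2.0)


class TestROIPairedCompare:
    LABELS = np.arange(1, 18)  # one voxel per ROI keeps the arithmetic exact

    def test_identical_conditions(self):
        rng = np.random.default_rng(0)
        maps = [rng.standard_normal(17) for _ in range(5)]
        df = roi_paired_compare(maps, [m.copy() for m in maps], self.LABELS)
        assert (df["t"] == 0).all()
        assert (df["p_bonferroni"] == 1.0).all()

    def test_constant_shift_degenerate(self):
        rng = np.random.default_rng(1)
        maps = [rng.standard_normal(17) for _ in range(5)]
        shifted = [m + 2.0 for m in maps]
        df = roi_paired_compare(maps, shifted, self.LABELS)
        assert df["degenerate"].all()
        assert (df["p_bonferroni"] == 0.0).all()

    def test_power_at_unit_effect_size(self):
        """delta = 1 SD of the pair difference, 20 pairs, 17 ROIs: at least
        80% of shifted ROIs survive Bonferroni."""
        rng = np.random.default_rng(5)
        maps_a = [rng.standard_normal(17) for _ in range(20)]
        maps_b = [rng.standard_normal(17) + np.sqrt(2.0) for _ in range(20)]
        df = roi_paired_compare(maps_a, maps_b, self.LABELS)
        assert df["significant"].mean() >= 0.80

    def test_background_label_ignored(self):
        labels = np.array([0, 1, 1, 2, 2])
        maps = [np.arange(5.0) + i for i in range(4)]
        df = roi_paired_compare(maps, maps, labels)
        assert sorted(df["roi"]) == [1, 2]


class TestRetestPipelineProperties:
    def test_wcv_decreases_with_thermal_noise(self, paradigm):
        """Zero truth jitter: recovered-rCVR wCV is noise-limited, so it
        falls monotonically as thermal noise drops (3-point grid)."""
        truth = generate_phantom(shape=(16, 16, 8), seed=5)
        gm = truth.gm_mask
        wcvs = []
        for sigma in (9.0, 3.0, 1.0):
            s1, s2 = simulate_retest(
                truth, paradigm, None, NoiseModel(sigma_thermal=sigma),
                jitter_cv=0.0, seeds=(41, 42),
            )
            r1 = analyze_session(s1)[1].rcvr
            r2 = analyze_session(s2)[1].rcvr
            wcvs.append(wcv_and_diff(r1, r2, gm).gm_mean_wcv)
        assert wcvs[0] > wcvs[1] > wcvs[2]

    def test_icc_degrades_with_noise(self, paradigm):
        """Across 20 simulated subjects with stable per-subject truth, the
        voxelwise ICC(3,1) of recovered gray-matter rCVR is higher at the
        default noise level than at 3x noise."""
        from bhcvr.synthetic import PhantomConfig

        rng = np.random.default_rng(77)
        truth0 = generate_phantom(shape=(16, 16, 8), seed=5)
        gm = truth0.gm_mask
        n_subjects = 20
        subject_amps = 1.0 + 0.25 * rng.standard_normal((n_subjects, 4))
        subject_amps = np.clip(subject_amps, 0.3, 2.0)
        med_icc = {}
        for sigma in (3.0, 9.0):
            rcvr = np.zeros((n_subjects, 2, int(gm.sum())))
            for i in range(n_subjects):
                cfg = PhantomConfig(
                    roi_amplitudes=tuple(0.6 * subject_amps[i]),
                )
                truth = generate_phantom(shape=(16, 16, 8), seed=5, config=cfg)
                s1, s2 = simulate_retest(
                    truth, paradigm, None, NoiseModel(sigma_thermal=sigma),
                    jitter_cv=0.0, seeds=(1000 + 2 * i, 1001 + 2 * i),
                )
                rcvr[i, 0] = analyze_session(s1)[1].rcvr[gm]
                rcvr[i, 1] = analyze_session(s2)[1].rcvr[gm]
            icc_map = icc31(rcvr)
            med_icc[sigma] = float(np.nanmedian(icc_map))
        assert med_icc[3.0] > med_icc[9.0]
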