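"""Lag-optimized breath-hold GLM, t-to-z mapping, CVR and rCVR."""

import numpy as np
import pytest
from scipy import stats

from bhcvr.glm import (
    ActivationMaps,
    activation_mask,
    compute_cvr,
    compute_rcvr,
    fit_bh_glm,
    t_to_z,
)
from bhcvr.preprocess import BoldSeries
from bhcvr.task_design import BHParadigm, build_regressor_set

from conftest import combined_truth_amplitude, session_t2star_fit


@pytest.fixture(scope="module")
def white_noise_fit(paradigm):
    """Single-lag GLM on pure white noise: the correctly specified null."""
    rng = np.random.default_rng(2024)
    n_vols = paradigm.n_volumes(0.9) - 10
    data = rng.standard_normal((2000, 1, 1, n_vols))
    series = BoldSeries(data=data, tr=0.9, n_discarded=10)
    regs = build_regressor_set(paradigm, 0.9, n_vols, 10, lags=[0.0])
    return fit_bh_glm(series, regs), data, n_vols


class TestLagOptimizedGLM:
    def test_noiseless_lag_recovery_is_exact(self, quiet_session, quiet_analysis):
        act = quiet_analysis[0]
        truth = quiet_session.truth
        gm = truth.gm_mask
        assert np.array_equal(act.lag[gm], truth.lag_map[gm])

    def test_noiseless_amplitude_within_one_percent(self, quiet_session, quiet_analysis):
        act = quiet_analysis[0]
        truth = quiet_session.truth
        gm = truth.gm_mask
        fit = session_t2star_fit(quiet_session)
        expected = combined_truth_amplitude(quiet_session, fit)
        rel = np.abs(act.beta - expected)[gm] / np.abs(expected[gm])
        assert rel.max() < 0.01

    def test_null_type_one_error_is_nominal(self, white_noise_fit):
        """With a single correctly specified lag, P(t > t_crit(0.01)) is 1%
        within the binomial 95% interval for 2000 voxels."""
        act, _, _ = white_noise_fit
        crit = stats.t.isf(0.01, act.dof)
        rate = (act.tstat > crit).mean()
        half = 1.96 * np.sqrt(0.01 * 0.99 / act.tstat.size)
        assert 0.01 - half <= rate <= 0.01 + half

    def test_max_over_lags_inflates_null(self, white_noise_fit, paradigm):
        """Selecting the best of 13 lags inflates the nominal 1% rate — a
        documented property of the analysis, replicated without correction."""
        _, data, n_vols = white_noise_fit
        series = BoldSeries(data=data, tr=0.9, n_discarded=10)
        regs = build_regressor_set(paradigm, 0.9, n_vols, 10)
        act = fit_bh_glm(series, regs)
        crit = stats.t.isf(0.01, act.dof)
        rate = (act.tstat > crit).mean()
        upper_ci = 0.01 + 1.96 * np.sqrt(0.01 * 0.99 / act.tstat.size)
        assert rate > upper_ci

    def test_duplicate_lags_tie_break_to_first(self, paradigm):
        rng = np.random.default_rng(7)
        n_vols = 300  # long enough to cover the breath-hold blocks
        data = rng.standard_normal((50, 1, 1, n_vols))
        series = BoldSeries(data=data, tr=0.9, n_discarded=0)
        regs = build_regressor_set(paradigm, 0.9, n_vols, 0, lags=[0.0, 0.0])
        act = fit_bh_glm(series, regs)
        assert np.all(act.lag == 0.0)

    def test_regressor_length_mismatch_rejected(self, paradigm):
        series = BoldSeries(data=np.zeros((2, 2, 2, 100)), tr=0.9, n_discarded=0)
        regs = build_regressor_set(paradigm, 0.9, 90, 0)
        with pytest.raises(ValueError):
            fit_bh_glm(series, regs)

    def test_dof_charges_confounds(self, paradigm):
        rng = np.random.default_rng(8)
        n_vols = 300
        data = rng.standard_normal((4, 1, 1, n_vols))
        regs = build_regressor_set(paradigm, 0.9, n_vols, 0, lags=[0.0])
        plain = fit_bh_glm(BoldSeries(data=data, tr=0.9), regs)
        charged = fit_bh_glm(
            BoldSeries(data=data, tr=0.9, confounds_removed=6), regs
        )
        assert plain.dof - charged.dof == 6

    def test_ar1_prewhitening_close_to_ols_on_white_noise(self, paradigm):
        rng = np.random.default_rng(9)
        n_vols = 200
        data = rng.standard_normal((100, 1, 1, n_vols))
        series = BoldSeries(data=data, tr=0.9)
        regs = build_regressor_set(paradigm, 0.9, n_vols, 0, lags=[0.0])
        ols = fit_bh_glm(series, regs, ar1=False)
        ar1 = fit_bh_glm(series, regs, ar1=True)
        assert np.corrcoef(ols.tstat.ravel(), ar1.tstat.ravel())[0, 1] > 0.98


class TestTToZ:
    def test_zero_maps_to_zero(self):
        for dof in (1, 10, 100):
            assert t_to_z(0.0, dof) == 0.0

    def test_large_dof_limit(self):
        assert t_to_z(2.5, 10**6) == pytest.approx(2.5, abs=1e-3)

    def test_reference_value(self):
        assert t_to_z(2.5, 30) == pytest.approx(2.3632, abs=1e-3)

    def test_sign_preserved_and_tail_stable(self):
        z = t_to_z(np.array([-12.0, 12.0]), 300)
        assert z[0] == -z[1]
        assert np.isfinite(z).all() and z[1] > 8

    def test_dof_below_one_rejected(self):
        with pytest.raises(ValueError):
            t_to_z(1.0, 0)


def _act_from(beta, mean, shape=None):
    beta = np.asarray(beta, dtype=float)
    mean = np.asarray(mean, dtype=float)
    ones = np.ones_like(beta, dtype=bool)
    return ActivationMaps(
        beta=beta, tstat=np.zeros_like(beta), zstat=np.zeros_like(beta),
        lag=np.zeros_like(beta), dof=100, mean_signal=mean, valid_mask=ones,
    )


class TestCVR:
    def test_percent_definition(self):
        cvr = compute_cvr(_act_from([1.0, 0.0], [100.0, 100.0]))
        assert cvr.cvr.tolist() == [1.0, 0.0]

    def test_nonpositive_mean_flagged(self):
        cvr = compute_cvr(_act_from([1.0], [0.0]))
        assert not cvr.valid_mask.any()

    def test_linear_regime_matches_generator(self, quiet_session, quiet_analysis):
        """Measured percent signal change tracks the generator's closed-form
        PSC within 2% when dR2* x TE is small."""
        act, cvr = quiet_analysis[0], quiet_analysis[1]
        truth = quiet_session.truth
        gm = truth.gm_mask
        fit = session_t2star_fit(quiet_session)
        expected_amp = combined_truth_amplitude(quiet_session, fit)
        with np.errstate(invalid="ignore", divide="ignore"):
            expected_psc = 100.0 * expected_amp / act.mean_signal
        rel = np.abs(cvr.cvr - expected_psc)[gm] / np.abs(expected_psc[gm])
        assert np.median(rel) < 0.02


class TestRCVR:
    def test_uniform_gm_normalizes_to_one(self):
        cvr = compute_cvr(_act_from(np.full((4, 4), 2.0), np.full((4, 4), 100.0)))
        gm = np.ones((4, 4), dtype=bool)
        out = compute_rcvr(cvr, gm)
        assert out.rcvr == pytest.approx(np.ones((4, 4)))

    def test_scale_invariance(self):
        base = compute_rcvr(
            compute_cvr(_act_from([1.0, 2.0, 3.0], [100.0] * 3)),
            np.ones(3, dtype=bool),
        )
        scaled = compute_rcvr(
            compute_cvr(_act_from([10.0, 20.0, 30.0], [100.0] * 3)),
            np.ones(3, dtype=bool),
        )
        assert scaled.rcvr == pytest.approx(base.rcvr)

    def test_two_region_hand_case(self):
        """Equal-size regions with amplitudes a and 2a give rCVR 2/3 and 4/3."""
        cvr = compute_cvr(_act_from([1.0, 1.0, 2.0, 2.0], [100.0] * 4))
        out = compute_rcvr(cvr, np.ones(4, dtype=bool))
        assert out.rcvr == pytest.approx([2 / 3, 2 / 3, 4 / 3, 4 / 3])

    def test_gm_mean_exactly_one_on_pipeline_output(self, quiet_session, quiet_analysis):
        cvr = quiet_analysis[1]
        gm = quiet_session.truth.gm_mask & cvr.valid_mask
        assert abs(cvr.rcvr[gm].mean() - 1.0) < 1e-9

    def test_nonpositive_gm_mean_rejected(self):
        cvr = compute_cvr(_act_from([-1.0, -2.0], [100.0, 100.0]))
        with pytest.raises(ValueError):
            compute_rcvr(cvr, np.ones(2, dtype=bool))


class TestActivationMask:
    def test_threshold_value(self):
        act = _act_from([0.0], [1.0])
        cutoff = stats.norm.isf(0.01)
        assert cutoff == pytest.approx(2.326, abs=0.001)
        z = np.array([cutoff - 0.01, cutoff + 0.01])
        act = ActivationMaps(
            beta=z, tstat=z, zstat=z, lag=np.zeros(2), dof=100,
            mean_signal=np.ones(2), valid_mask=np.ones(2, dtype=bool),
        )
        assert activation_mask(act, 0.01).tolist() == [False, True]

    def test_all_zero_z_empty_mask(self):
        act = _act_from([0.0, 0.0], [1.0, 1.0])
        assert not activation_mask(act, 0.01).any()

    def test_median_cutoff(self):
        z = np.array([-0.5, 0.5])
        act = ActivationMaps(
            beta=z, tstat=z, zstat=z, lag=np.zeros(2), dof=100,
            mean_signal=np.ones(2), valid_mask=np.ones(2, dtype=bool),
        )
        assert activation_mask(act, 0.5).tolist() == [False, True]

    def test_invalid_p_rejected(self):
        act = _act_from([0.0], [1.0])
        with pytest.raises(ValueError):
            activation_mask(act, 1.5)
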