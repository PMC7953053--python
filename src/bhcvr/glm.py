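"""Voxelwise breath-hold GLM with lag optimization, and CVR/rCVR mapping.

For each voxel and each candidate lag, an ordinary least-squares fit of
[intercept, lagged BH regressor, optional nuisance columns] is computed; the
lag whose BH column attains the highest positive t-statistic is selected
(ties break toward the smallest lag, for determinism). t-statistics are
converted to z-scores through the probability-preserving two-sided mapping
z = Phi^{-1}(F_t(t; dof)) with log-tail evaluation, using degrees of freedom
reduced by every design column and every previously regressed confound.

CVR is the percent signal change of the peak BH response: 100 * beta / mean
signal (beta is in the units of the peak-normalized regressor, so it is the
peak response amplitude). Relative CVR divides by the mean CVR over gray
matter, which cancels the TE dependence of the percent signal change.

Caveat, inherited from the underlying analysis design: selecting the
maximum t over 13 lags inflates the null distribution of the reported t; no
multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .preprocess import BoldSeries
from .task_design import RegressorSet

__all__ = [
    "ActivationMaps",
    "CVRMaps",
    "fit_bh_glm",
    "t_to_z",
    "compute_cvr",
    "compute_rcvr",
    "activation_mask",
]


@dataclass(frozen=True)
class ActivationMaps:
    """Voxelwise outputs of the lag-optimized BH GLM."""

    beta: np.ndarray        # peak BH response amplitude, signal units
    tstat: np.ndarray
    zstat: np.ndarray
    lag: np.ndarray         # selected lag, s
    dof: int                # effective degrees of freedom
    mean_signal: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class CVRMaps:
    """CVR (percent signal change) and gray-matter-normalized rCVR."""

    cvr: np.ndarray
    rcvr: np.ndarray | None
    gm_mean_cvr: float | None
    valid_mask: np.ndarray


def _ols_tstats(Y: np.ndarray, X: np.ndarray, dof: int) -> tuple[np.ndarray, np.ndarray]:
    """OLS of Y (n_t x n_vox) on X (n_t x p); returns (beta_task, t_task).

    The task column is assumed to be the last column of X. ``dof`` is the
    effective residual dof used in the variance estimate.
    """
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y                      # (p, n_vox)
    resid = Y - X @ beta
    rss = np.einsum("ij,ij->j", resid, resid)
    sigma2 = rss / dof
    xtx_inv_task = np.linalg.inv(X.T @ X)[-1, -1]
    se = np.sqrt(sigma2 * xtx_inv_task)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[-1] / se, np.inf * np.sign(beta[-1]))
    return beta[-1], t


def _ar1_transform(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise Cochrane-Orcutt AR(1) prewhitening.

    rho is estimated per voxel from the lag-1 autocorrelation of the OLS
    residuals; y and X are quasi-differenced. Returns transformed (Y', X')
    with X' of shape (n_vox, n_t-1, p).
    """
    pinv = np.linalg.pinv(X)
    resid = Y - X @ (pinv @ Y)
    num = np.einsum("ij,ij->j", resid[1:], resid[:-1])
    den = np.einsum("ij,ij->j", resid[:-1], resid[:-1])
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    rho = np.clip(rho, -0.99, 0.99)
    Yt = (Y[1:] - rho * Y[:-1]).T[:, :, None]               # (vox, t-1, 1)
    Xt = X[None, 1:, :] - rho[:, None, None] * X[None, :-1, :]
    return Yt, Xt


def _batched_tstats(Yt: np.ndarray, Xt: np.ndarray, dof: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel OLS with voxel-specific design (AR(1) path)."""
    xtx = np.einsum("vtp,vtq->vpq", Xt, Xt)
    xty = np.einsum("vtp,vt->vp", Xt, Yt[:, :, 0])
    xtx_inv = np.linalg.inv(xtx)
    beta = np.einsum("vpq,vq->vp", xtx_inv, xty)
    resid = Yt[:, :, 0] - np.einsum("vtp,vp->vt", Xt, beta)
    rss = np.einsum("vt,vt->v", resid, resid)
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * xtx_inv[:, -1, -1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[:, -1] / se, np.inf * np.sign(beta[:, -1]))
    return beta[:, -1], t


def fit_bh_glm(
    series: BoldSeries,
    regressors: RegressorSet,
    nuisance=None,
    ar1: bool = False,
    mask: np.ndarray | None = None,
    mean_signal: np.ndarray | None = None,
) -> ActivationMaps:
    """Fit the lag-optimized BH GLM over every voxel (in ``mask`` if given).

    ``mean_signal`` supplies the percent-signal-change denominator; by
    default the temporal mean of the input series is used (detrending
    preserves the mean, so this matches the pre-detrend baseline in the
    standard pipeline order).
    """
    n_t = series.n_t
    if regressors.n_volumes != n_t:
        raise ValueError("regressor rows must match the series length")
    if regressors.n_discarded != series.n_discarded:
        raise ValueError("regressor sampling offset does not match the series")

    shape = series.data.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    Y = series.data[mask].T  # (n_t, n_vox)
    n_vox = Y.shape[1]

    nuis_cols = []
    if nuisance is not None:
        N = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if N.shape[0] != n_t:
            N = N.T
        if N.shape[0] != n_t:
            raise ValueError("nuisance table must have n_t rows")
        nuis_cols = [N - N.mean(axis=0)]

    base = [np.ones((n_t, 1))] + nuis_cols
    p = 1 + (nuis_cols[0].shape[1] if nuis_cols else 0) + 1  # + task column
    dof = n_t - p - series.confounds_removed
    if dof <= 0:
        raise ValueError("no residual degrees of freedom left")

    best_t = np.full(n_vox, -np.inf)
    best_beta = np.zeros(n_vox)
    best_lag = np.full(n_vox, regressors.lags[0])
    for lag, col in zip(regressors.lags, regressors.matrix.T):
        X = np.column_stack(base + [col])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"design matrix is rank deficient at lag {lag:g}")
        if ar1:
            Yt, Xt = _ar1_transform(Y, X)
            beta, t = _batched_tstats(Yt, Xt, dof - 1)
        else:
            beta, t = _ols_tstats(Y, X, dof)
        better = t > best_t  # strict: equal t keeps the earlier (smaller) lag
        best_t = np.where(better, t, best_t)
        best_beta = np.where(better, beta, best_beta)
        best_lag = np.where(better, lag, best_lag)

    finite = np.isfinite(best_t)
    z = np.zeros(n_vox)
    z[finite] = t_to_z(best_t[finite], dof)
    z[~finite] = np.sign(best_t[~finite]) * np.inf

    def unflat(v, fill=0.0):
        out = np.full(shape, fill)
        out[mask] = v
        return out

    mean_map = series.data.mean(axis=-1) if mean_signal is None else np.asarray(mean_signal)
    return ActivationMaps(
        beta=unflat(best_beta),
        tstat=unflat(best_t),
        zstat=unflat(z),
        lag=unflat(best_lag),
        dof=int(dof),
        mean_signal=mean_map,
        valid_mask=mask & np.isfinite(unflat(best_t, np.nan)),
    )


def t_to_z(t, dof: int):
    """Probability-preserving t -> z conversion with tail-stable evaluation.

    z = Phi^{-1}(F_t(t; dof)), computed through log survival functions so
    extreme t-values (|t| > 8) do not saturate. Sign is preserved; t = 0
    maps to z = 0 for any dof.
    """
    if dof < 1:
        raise ValueError("dof must be at least 1")
    t = np.asarray(t, dtype=float)
    logp = stats.t.logsf(np.abs(t), dof)
    z_mag = -special.ndtri_exp(logp)
    return np.sign(t) * z_mag


def compute_cvr(act: ActivationMaps) -> CVRMaps:
    """CVR as percent signal change: 100 * beta / mean signal.

    Voxels with nonpositive mean signal are flagged invalid.
    """
    if act.mean_signal is None:
        raise ValueError("activation maps carry no mean-signal map")
    valid = act.valid_mask & (act.mean_signal > 0)
    cvr = np.zeros_like(act.beta)
    np.divide(100.0 * act.beta, act.mean_signal, out=cvr, where=valid)
    return CVRMaps(cvr=cvr, rcvr=None, gm_mean_cvr=None, valid_mask=valid)


def compute_rcvr(cvr: CVRMaps, gm_mask: np.ndarray) -> CVRMaps:
    """Relative CVR: voxel CVR divided by the mean CVR over gray matter."""
    gm = np.asarray(gm_mask, dtype=bool) & cvr.valid_mask
    if not gm.any():
        raise ValueError("gray-matter mask is empty (after validity exclusion)")
    gm_mean = float(cvr.cvr[gm].mean())
    if gm_mean <= 0:
        raise ValueError("mean gray-matter CVR is not positive; fit looks pathological")
    rcvr = np.zeros_like(cvr.cvr)
    np.divide(cvr.cvr, gm_mean, out=rcvr, where=cvr.valid_mask)
    return replace(cvr, rcvr=rcvr, gm_mean_cvr=gm_mean)


def activation_mask(act: ActivationMaps, p: float = 0.01) -> np.ndarray:
    """One-sided positive activation mask: z > Phi^{-1}(1 - p).

    One-sided matches the positive-t lag selection rule. p = 0.01
    corresponds to a z cutoff of 2.326.
    """
    if not (0 < p < 1):
        raise ValueError("p must be in (0, 1)")
    cutoff = stats.norm.isf(p)
    return act.valid_mask & (act.zstat > cutoff)
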