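"""Voxelwise T2* estimation and T2*-weighted echo combination.

The time-mean signal of each echo follows S(TE) ~ S0 exp(-TE/T2*), so a
log-linear least-squares fit over echoes yields per-voxel T2* and S0. Echoes
are then combined with static weights W_n proportional to TE_n e^{-TE_n/T2*}
(normalized to sum to 1), which weights each echo by its expected BOLD
contrast at the voxel's T2*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["T2StarFit", "fit_t2star", "combination_weights", "combine_echoes", "average_echoes"]

T2STAR_CLAMP_MS = (5.0, 300.0)


@dataclass(frozen=True)
class T2StarFit:
    """Voxelwise mono-exponential decay fit.

    ``valid_mask`` marks voxels with a usable fit (all echo means positive
    and a decaying slope); elsewhere T2* is set to the clamp ceiling and S0
    to the first-echo mean so downstream weights stay finite.
    """

    t2star_map: np.ndarray  # ms, clamped to T2STAR_CLAMP_MS inside valid_mask
    s0_map: np.ndarray
    valid_mask: np.ndarray
    te_list: tuple[float, ...]


def fit_t2star(mean_per_echo, te_list) -> T2StarFit:
    """Log-linear T2* fit from per-echo time-mean signals.

    Parameters
    ----------
    mean_per_echo : array, shape (n_echoes, ...) or sequence of maps
        Time-averaged signal of each echo.
    te_list : sequence of float
        Echo times in milliseconds, one per echo.
    """
    means = np.asarray(mean_per_echo, dtype=float)
    te = np.asarray(te_list, dtype=float)
    if means.shape[0] != te.size:
        raise ValueError("first axis of mean_per_echo must index echoes")
    if te.size < 2:
        raise ValueError("at least two echoes are required to fit T2*")

    spatial = means.shape[1:]
    flat = means.reshape(te.size, -1)
    valid = np.all(flat > 0, axis=0)

    slope = np.zeros(flat.shape[1])
    intercept = np.zeros(flat.shape[1])
    if valid.any():
        y = np.log(flat[:, valid])
        X = np.column_stack([np.ones_like(te), te])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        intercept[valid] = coef[0]
        slope[valid] = coef[1]
    valid &= slope < 0  # non-decaying voxels are noise/background

    lo, hi = T2STAR_CLAMP_MS
    t2star = np.full(flat.shape[1], hi)
    with np.errstate(divide="ignore"):
        t2star[valid] = np.clip(-1.0 / slope[valid], lo, hi)
    s0 = np.where(valid, np.exp(intercept), flat[0])

    return T2StarFit(
        t2star_map=t2star.reshape(spatial),
        s0_map=s0.reshape(spatial),
        valid_mask=valid.reshape(spatial),
        te_list=tuple(float(t) for t in te),
    )


def combination_weights(fit: T2StarFit) -> np.ndarray:
    """Per-voxel combination weights, shape (n_echoes, ...); sum to 1."""
    te = np.asarray(fit.te_list)
    t2 = fit.t2star_map[None, ...]
    w = te.reshape((-1,) + (1,) * fit.t2star_map.ndim) * np.exp(-te.reshape((-1,) + (1,) * fit.t2star_map.ndim) / t2)
    return w / w.sum(axis=0, keepdims=True)


def combine_echoes(echoes, fit: T2StarFit) -> np.ndarray:
    """T2*-weighted combination of per-echo 4-D series.

    combined(v, t) = sum_n W_n(v) S_n(v, t); weights are constant over time
    and sum to 1, so identical echoes pass through unchanged.
    """
    echoes = [np.asarray(e, dtype=float) for e in echoes]
    if len(echoes) != len(fit.te_list):
        raise ValueError("echo count does not match the fitted echo times")
    shapes = {e.shape for e in echoes}
    if len(shapes) != 1:
        raise ValueError("echo arrays must share one shape")
    if echoes[0].shape[:-1] != fit.t2star_map.shape:
        raise ValueError("echo spatial shape does not match the fit maps")
    if len(echoes) == 1:
        return echoes[0].copy()
    w = combination_weights(fit)
    out = np.zeros_like(echoes[0])
    for wn, en in zip(w, echoes):
        out += wn[..., None] * en
    return out


def average_echoes(echoes) -> np.ndarray:
    """Plain echo average, kept as a comparison baseline."""
    echoes = [np.asarray(e, dtype=float) for e in echoes]
    return np.mean(echoes, axis=0)
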