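"""Temporal preprocessing of BOLD series and tSNR computation.

Operations act on a :class:`BoldSeries` container that carries the 4-D data
together with the bookkeeping the GLM needs later: how many initial volumes
were discarded (shifts the regressor sampling times) and how many confound
columns have been regressed out (reduces the effective degrees of freedom).

A note on the task notch: independent-component noise estimation can
misclassify the breath-hold response as noise because of its large variance.
The fix is to estimate noise components on a copy of the data with the task
frequency (1/56 Hz) suppressed, then regress those components out of the
ORIGINAL unfiltered series. :func:`regress_confounds` enforces that contract
when a confound table is tagged as estimated on filtered data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "BoldSeries",
    "TSNRMaps",
    "discard_initial",
    "polynomial_detrend",
    "polynomial_nuisance",
    "gaussian_smooth",
    "notch_filter_task",
    "regress_confounds",
    "compute_tsnr",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BoldSeries:
    """A 4-D BOLD series with timing and degrees-of-freedom bookkeeping."""

    data: np.ndarray           # (x, y, z, t)
    tr: float
    n_discarded: int = 0
    confounds_removed: int = 0
    mask: np.ndarray | None = None
    is_task_filtered: bool = False
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.ndim != 4 or self.data.shape[-1] < 1:
            raise ValueError("data must be 4-D with at least one frame")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.confounds_removed < 0:
            raise ValueError("confounds_removed must be nonnegative")

    @property
    def n_t(self) -> int:
        return self.data.shape[-1]

    def _step(self, data: np.ndarray, note: str, **kw) -> "BoldSeries":
        return replace(self, data=data, provenance=self.provenance + (note,), **kw)


@dataclass(frozen=True)
class TSNRMaps:
    """Temporal SNR maps; ``valid_mask`` is False where temporal SD is zero."""

    tsnr: np.ndarray
    tsnr_norm: np.ndarray  # tsnr * sqrt(n_t)
    valid_mask: np.ndarray
    n_t: int


def discard_initial(series: BoldSeries, n: int = 10) -> BoldSeries:
    """Drop the first ``n`` frames (pre-steady-state volumes).

    The discard count is tracked so regressor sampling times start at
    n_discarded * TR.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    if n >= series.n_t:
        raise ValueError("cannot discard all frames")
    if n == 0:
        return series
    return series._step(
        series.data[..., n:], f"discard_initial(n={n})",
        n_discarded=series.n_discarded + n,
    )


def _poly_basis(n_t: int, order: int) -> np.ndarray:
    # Legendre polynomials on [-1, 1]: orthogonal, numerically stable
    tau = np.linspace(-1.0, 1.0, n_t)
    return np.polynomial.legendre.legvander(tau, order)


def polynomial_nuisance(n_t: int, order: int = 3) -> np.ndarray:
    """Polynomial drift columns (constant term excluded) for joint GLM fits.

    Fitting drift jointly with the task regressor is preferred over
    detrending first: the BH regressor's undershoot carries low-frequency
    energy, so a prior detrend absorbs part of the task response and biases
    beta downward.
    """
    return _poly_basis(n_t, order)[:, 1:]


def polynomial_detrend(series: BoldSeries, order: int = 3) -> BoldSeries:
    """Remove a per-voxel polynomial trend of the given order, keeping the mean.

    The residual is orthogonal to the polynomial basis; repeating the
    operation is a no-op (projection idempotence).
    """
    n_t = series.n_t
    if n_t <= order + 1:
        raise ValueError("not enough frames for the requested polynomial order")
    basis = _poly_basis(n_t, order)
    flat = series.data.reshape(-1, n_t).T  # (t, vox)
    coef, *_ = np.linalg.lstsq(basis, flat, rcond=None)
    resid = flat - basis @ coef
    out = (resid + flat.mean(axis=0)).T.reshape(series.data.shape)
    return series._step(out, f"polynomial_detrend(order={order})")


def gaussian_smooth(series: BoldSeries, fwhm: float = 4.0, voxel_size=3.0) -> BoldSeries:
    """Spatial Gaussian smoothing per frame.

    ``fwhm`` and ``voxel_size`` are in mm; sigma = fwhm / (2 sqrt(2 ln 2)).
    Zero-padded boundaries, so the total image sum is preserved for interior
    support.
    """
    if fwhm < 0:
        raise ValueError("fwhm must be nonnegative")
    if fwhm == 0:
        return series
    vs = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    sigma_vox = (fwhm * FWHM_TO_SIGMA) / vs
    out = ndimage.gaussian_filter(
        series.data, sigma=tuple(sigma_vox) + (0.0,), mode="constant", cval=0.0
    )
    return series._step(out, f"gaussian_smooth(fwhm={fwhm})")


def _notch_matrix_apply(flat_tv: np.ndarray, tr: float, f0: float, half_width: float) -> np.ndarray:
    """Suppress content in [f0-hw, f0+hw]: exact sin/cos projection at f0
    (demeaned so DC is untouched) followed by zeroing the remaining DFT bins
    in the band. The projection handles the generic case of a stop-band
    frequency that falls between DFT bins, where plain bin zeroing leaves
    large spectral leakage."""
    n_t = flat_tv.shape[0]
    t = np.arange(n_t) * tr
    basis = np.column_stack([np.sin(2 * np.pi * f0 * t), np.cos(2 * np.pi * f0 * t)])
    basis -= basis.mean(axis=0)
    coef, *_ = np.linalg.lstsq(basis, flat_tv, rcond=None)
    resid = flat_tv - basis @ coef

    spec = np.fft.rfft(resid, axis=0)
    freqs = np.fft.rfftfreq(n_t, tr)
    band = (freqs >= f0 - half_width) & (freqs <= f0 + half_width) & (freqs > 0)
    spec[band] = 0
    return np.fft.irfft(spec, n_t, axis=0)


def notch_filter_task(series: BoldSeries, f0: float = 1.0 / 56.0,
                      half_width: float = 0.005, harmonics: int = 0) -> BoldSeries:
    """Suppress the task frequency band [f0 - hw, f0 + hw]; DC is untouched.

    ``harmonics`` > 0 additionally suppresses bands around 2 f0, 3 f0, ...
    The result is tagged task-filtered: downstream confound regression will
    refuse to treat it as the original series for component removal.
    """
    nyquist = 0.5 / series.tr
    if not (0 < f0 < nyquist):
        raise ValueError("f0 must lie below the Nyquist frequency")
    flat = series.data.reshape(-1, series.n_t).T
    for k in range(1, harmonics + 2):
        fk = k * f0
        if fk >= nyquist:
            break
        flat = _notch_matrix_apply(flat, series.tr, fk, half_width)
    out = flat.T.reshape(series.data.shape)
    return series._step(
        out, f"notch_filter_task(f0={f0:g}, hw={half_width:g})",
        is_task_filtered=True,
    )


def regress_confounds(series: BoldSeries, confounds, *,
                      estimated_on_filtered: bool = False) -> BoldSeries:
    """Regress a confound table (n_t x k) out of every voxel.

    Columns are demeaned before projection so the signal mean survives. The
    removed column count is added to ``confounds_removed`` for downstream
    degrees-of-freedom adjustment.

    ``estimated_on_filtered`` declares that the confounds were estimated on
    a task-notch-filtered copy of the data; such components must be removed
    from the original, unfiltered series, and passing a filtered series
    raises an error.
    """
    if estimated_on_filtered and series.is_task_filtered:
        raise ValueError(
            "components estimated on task-filtered data must be regressed "
            "out of the original unfiltered series"
        )
    C = np.atleast_2d(np.asarray(confounds, dtype=float))
    if C.shape[0] != series.n_t:
        C = C.T
    if C.shape[0] != series.n_t:
        raise ValueError("confound table must have n_t rows")
    k = C.shape[1]
    C = C - C.mean(axis=0)
    rank = np.linalg.matrix_rank(C)
    if rank < k:
        norms = np.linalg.norm(C, axis=0)
        bad = [str(i) for i in np.where(norms < 1e-12 * max(norms.max(), 1))[0]]
        raise ValueError(
            "confound table is rank deficient after demeaning"
            + (f" (degenerate columns: {', '.join(bad)})" if bad else "")
        )
    flat = series.data.reshape(-1, series.n_t).T
    coef, *_ = np.linalg.lstsq(C, flat, rcond=None)
    out = (flat - C @ coef).T.reshape(series.data.shape)
    return series._step(
        out, f"regress_confounds(k={k})",
        confounds_removed=series.confounds_removed + k,
    )


def compute_tsnr(series: BoldSeries) -> TSNRMaps:
    """tSNR = temporal mean / temporal SD (sample SD, n-1 denominator).

    The normalized map multiplies by sqrt(n_t) to make runs of different
    length comparable. Zero-SD voxels are flagged, not infinite.
    """
    if series.n_t < 2:
        raise ValueError("need at least two frames for tSNR")
    mean = series.data.mean(axis=-1)
    sd = series.data.std(axis=-1, ddof=1)
    valid = sd > 0
    tsnr = np.zeros_like(mean)
    np.divide(mean, sd, out=tsnr, where=valid)
    return TSNRMaps(
        tsnr=tsnr, tsnr_norm=tsnr * np.sqrt(series.n_t),
        valid_mask=valid, n_t=series.n_t,
    )
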