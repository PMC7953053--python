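"""Breath-hold task timing and regressor construction.

The paradigm is a block design: a paced-breathing lead-in, several cycles of
paced breathing / end-expiration breath hold / recovery, and a paced
lead-out. The expected BOLD response to each hold is modeled by convolving a
hold-period boxcar with the respiration response function (RRF), a canonical
impulse response with an early positive peak (~3 s) and a long negative
undershoot. Because the hemodynamic delay of the breath-hold response varies
regionally by several seconds, the convolved regressor is replicated at a
grid of temporal lags; the voxelwise GLM later selects the best-fitting lag.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BHParadigm",
    "RRFKernel",
    "RegressorSet",
    "rrf",
    "boxcar",
    "build_regressor_set",
    "default_lag_grid",
    "convolved_response",
]

DEFAULT_LAGS = tuple(range(-8, 17, 2))  # -8..16 s in 2-s steps, 13 lags


@dataclass(frozen=True)
class BHParadigm:
    """Block timing of the breath-hold task, all durations in seconds.

    Defaults describe a 320-s run: 66 s paced lead-in, four cycles of
    24 s paced / 16 s hold / 16 s recovery, 30 s paced lead-out. Paced
    breathing alternates 3-s inhales and exhales (6-s period, ~0.17 Hz).
    """

    lead_in: float = 66.0
    n_cycles: int = 4
    paced: float = 24.0
    hold: float = 16.0
    recovery: float = 16.0
    lead_out: float = 30.0
    paced_breath_period: float = 6.0

    def __post_init__(self) -> None:
        for name in ("lead_in", "paced", "hold", "recovery", "lead_out"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be nonnegative")
        if self.paced_breath_period <= 0:
            raise ValueError("paced_breath_period must be positive")

    @property
    def cycle_period(self) -> float:
        """Duration of one paced+hold+recovery cycle (56 s with defaults)."""
        return self.paced + self.hold + self.recovery

    @property
    def task_frequency(self) -> float:
        """Fundamental frequency of the block cycle in Hz (1/56 with defaults)."""
        return 1.0 / self.cycle_period

    def total_duration(self) -> float:
        """Total run duration in seconds (320 with defaults)."""
        return self.lead_in + self.n_cycles * self.cycle_period + self.lead_out

    def n_volumes(self, tr: float) -> int:
        """Number of volumes acquired in the run: floor(duration / TR)."""
        if tr <= 0:
            raise ValueError("tr must be positive")
        return int(np.floor(self.total_duration() / tr))

    def hold_onsets(self) -> np.ndarray:
        """Start times of each breath-hold block."""
        return self.lead_in + self.paced + np.arange(self.n_cycles) * self.cycle_period

    def to_json(self) -> str:
        return json.dumps(
            {
                "lead_in": self.lead_in,
                "n_cycles": self.n_cycles,
                "paced": self.paced,
                "hold": self.hold,
                "recovery": self.recovery,
                "lead_out": self.lead_out,
                "paced_breath_period": self.paced_breath_period,
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "BHParadigm":
        return cls(**json.loads(s))


def rrf(t) -> np.ndarray:
    """Respiration response function evaluated pointwise.

    RRF(t) = 0.6 t^2.1 e^{-t/1.6} - 0.0023 t^3.54 e^{-t/4.25} for t >= 0,
    0 for t < 0. Peaks near t = 3.1 s; undershoots between ~10 and 25 s.
    """
    t = np.asarray(t, dtype=float)
    tp = np.where(t > 0, t, 0.0)
    with np.errstate(invalid="ignore"):
        val = 0.6 * tp**2.1 * np.exp(-tp / 1.6) - 0.0023 * tp**3.54 * np.exp(-tp / 4.25)
    return np.where(t > 0, val, 0.0)


@dataclass(frozen=True)
class RRFKernel:
    """Sampled RRF kernel at resolution ``dt`` over ``length`` seconds.

    The default 60-s truncation leaves a residual undershoot of ~3e-3
    (about 0.4% of the kernel peak) in the discarded tail, negligible for
    regressor construction.
    """

    dt: float = 0.1
    length: float = 60.0
    samples: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.length <= 0:
            raise ValueError("dt and length must be positive")
        if self.samples is None:
            t = np.arange(0.0, self.length, self.dt)
            object.__setattr__(self, "samples", rrf(t))
        if self.samples[0] != 0.0:
            raise ValueError("kernel must start at zero")
        if abs(float(self.samples[-1])) > 5e-3:
            raise ValueError("kernel has not decayed by the chosen length")


@dataclass(frozen=True)
class RegressorSet:
    """Lag-shifted BH regressors sampled at volume-acquisition times.

    ``matrix`` is n_volumes x n_lags; column j is the RRF-convolved hold
    boxcar delayed by ``lags[j]`` seconds. All columns share one
    normalization scale taken from the lag-0 column peak, so fitted betas
    are comparable across lags.
    """

    lags: tuple[float, ...]
    matrix: np.ndarray
    tr: float
    n_discarded: int

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.lags):
            raise ValueError("matrix must be n_volumes x n_lags")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, lag: float) -> np.ndarray:
        return self.matrix[:, self.lags.index(lag)]

    def to_tsv(self, path) -> None:
        header = "\t".join(f"{l:g}" for l in self.lags)
        np.savetxt(path, self.matrix, delimiter="\t", header=header, comments="")


def default_lag_grid() -> tuple[float, ...]:
    """Lag grid -8..16 s in 2-s steps (13 lags)."""
    return tuple(float(l) for l in DEFAULT_LAGS)


def boxcar(p: BHParadigm, dt: float) -> np.ndarray:
    """Hold-period indicator sampled at resolution ``dt`` over the full run.

    1 exactly within breath-hold blocks, 0 otherwise.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if p.n_cycles > 0 and dt > p.hold:
        raise ValueError("dt exceeds the hold duration; holds cannot be represented")
    t = np.arange(0.0, p.total_duration(), dt)
    out = np.zeros_like(t)
    for onset in p.hold_onsets():
        out[(t >= onset) & (t < onset + p.hold)] = 1.0
    return out


def convolved_response(p: BHParadigm, dt: float = 0.1, kernel: RRFKernel | None = None,
                       normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """RRF-convolved hold boxcar on the fine time grid.

    Returns ``(t, x)`` where ``t`` spans the run at resolution ``dt`` and
    ``x`` is the discrete convolution (scaled by ``dt`` to approximate the
    continuous integral), peak-normalized to 1 when ``normalize`` is True.
    This is the shared ground-truth response shape used both by the
    regressor builder and the synthetic-data generator.
    """
    if kernel is None:
        kernel = RRFKernel(dt=dt)
    elif abs(kernel.dt - dt) > 1e-12:
        raise ValueError("kernel dt must match requested dt")
    box = boxcar(p, dt)
    x = np.convolve(box, kernel.samples)[: box.size] * dt
    t = np.arange(box.size) * dt
    if normalize:
        peak = x.max()  # positive task peak; the undershoot lobe is larger in |.|
        if peak > 0:
            x = x / peak
    return t, x


def build_regressor_set(
    p: BHParadigm,
    tr: float,
    n_vols: int,
    n_discarded: int = 0,
    lags=DEFAULT_LAGS,
    dt: float = 0.1,
    kernel: RRFKernel | None = None,
) -> RegressorSet:
    """Build the lag-shifted BH regressor matrix sampled at volume times.

    The hold boxcar is convolved with the RRF at resolution ``dt``; for each
    lag L the convolved response is shifted by round(L/dt) fine-grid samples
    (positive L = response occurs later) and then sampled at the acquisition
    times t_i = (n_discarded + i) * tr for i = 0..n_vols-1. The lag-0 sampled
    column is peak-normalized and the same scale applied to every column.
    """
    lags = tuple(float(l) for l in lags)
    if not lags:
        raise ValueError("lag list must be nonempty")
    if tr <= 0:
        raise ValueError("tr must be positive")
    if (n_discarded + n_vols) * tr > p.total_duration() + tr:
        raise ValueError("requested volumes extend past the end of the run")

    _, x = convolved_response(p, dt=dt, kernel=kernel, normalize=False)
    t_vols = (n_discarded + np.arange(n_vols)) * tr
    n_fine = x.size

    def shifted(lag: float) -> np.ndarray:
        k = int(round(lag / dt))
        out = np.zeros(n_fine)
        if k >= 0:
            out[k:] = x[: n_fine - k] if k < n_fine else 0.0
        else:
            out[: n_fine + k] = x[-k:]
        return out

    fine_t = np.arange(n_fine) * dt
    cols = [np.interp(t_vols, fine_t, shifted(l), left=0.0, right=0.0) for l in lags]
    matrix = np.column_stack(cols)

    lag0 = shifted(0.0)
    scale = np.interp(t_vols, fine_t, lag0, left=0.0, right=0.0).max()
    if scale > 0:
        matrix = matrix / scale
    return RegressorSet(lags=lags, matrix=matrix, tr=tr, n_discarded=n_discarded)
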