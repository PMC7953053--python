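"""Synthetic multi-echo breath-hold BOLD sessions with known ground truth.

The generator produces a small digital head phantom (gray matter shell,
white matter core, a low-T2* "dropout" pocket emulating orbitofrontal
susceptibility loss, and background) and renders per-echo 4-D time series
from a mono-exponential signal model:

    S(v, t, e) = S0(v) exp(-TE_e R2*(v, t) / 1000)
                 * [1 + respiratory oscillation + polynomial drift]
                 + thermal noise,

    R2*(v, t) = R2*0(v) - dR2*(v) x(t - lag(v)),

where x is the peak-normalized RRF-convolved hold boxcar. Modeling the task
as an R2* decrease (vasodilation lengthens T2*) makes the percent signal
change grow with TE exactly as the multi-echo physics predicts, so echo
combination, CVR scaling and lag recovery can all be validated against
closed forms. All randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .task_design import BHParadigm, convolved_response
from .theory import SequenceParams

__all__ = [
    "GroundTruth",
    "NoiseModel",
    "PhantomConfig",
    "SyntheticSession",
    "generate_phantom",
    "simulate_session",
    "simulate_retest",
    "combined_truth_amplitude",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Knobs of the digital phantom.

    ``roi_amplitudes`` are peak task-induced R2* decreases (1/s) per gray
    matter ROI; with the default echo times they correspond to peak percent
    signal changes of roughly 1-3% on the combined series, typical of
    breath-hold responses at 3 T. ``roi_lags`` (s) lie on the analysis lag
    grid by default so exact recovery is well defined.
    """

    amplitude_scale: float = 1.0
    roi_amplitudes: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9)
    roi_lags: tuple[float, ...] = (-4.0, 0.0, 6.0, 10.0)
    gm_t2star_ms: float = 50.0
    wm_t2star_ms: float = 45.0
    dropout_t2star_ms: float = 20.0
    s0_gm: float = 1000.0
    s0_wm: float = 900.0
    s0_dropout: float = 700.0
    s0_texture_cv: float = 0.02  # mild voxelwise S0 variation


@dataclass(frozen=True)
class NoiseModel:
    """Nuisance processes added to the clean signal.

    ``sigma_thermal`` is the additive Gaussian noise SD per echo in signal
    units (default 3, placing normalized gray-matter tSNR of the combined
    series in the low thousands, the in-vivo order of magnitude). ``resp_amp`` is the fractional amplitude of
    the paced-breathing oscillation at ``resp_freq`` (default 1/6 Hz for
    3-s inhale / 3-s exhale pacing). ``drift_coeffs`` are fractional
    polynomial drift coefficients in normalized time on [-1, 1], constant
    term excluded.
    """

    sigma_thermal: float = 3.0
    resp_amp: float = 0.003
    resp_freq: float = 1.0 / 6.0
    drift_coeffs: tuple[float, ...] = (0.005, -0.002, 0.001)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_thermal < 0:
            raise ValueError("sigma_thermal must be nonnegative")
        if self.resp_freq <= 0:
            raise ValueError("resp_freq must be positive")


@dataclass(frozen=True)
class GroundTruth:
    """Voxelwise truth maps of the phantom."""

    shape: tuple[int, int, int]
    s0_map: np.ndarray
    r2star0_map: np.ndarray      # baseline R2* in 1/s (= 1000 / T2*[ms])
    delta_r2star_map: np.ndarray  # peak task-induced R2* decrease, 1/s, >= 0
    lag_map: np.ndarray          # s
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    dropout_mask: np.ndarray
    head_mask: np.ndarray
    labels: np.ndarray           # integer ROI map (0 = none)

    def __post_init__(self) -> None:
        if np.any(self.delta_r2star_map[~self.gm_mask] != 0):
            raise ValueError("delta_r2star must be zero outside gray matter")
        if np.any(self.r2star0_map[self.head_mask] <= 0):
            raise ValueError("baseline R2* must be positive inside the head")


@dataclass(frozen=True)
class SyntheticSession:
    """One simulated multi-echo acquisition."""

    echoes: tuple[np.ndarray, ...]  # per-TE 4-D arrays (x, y, z, t)
    params: SequenceParams
    paradigm: BHParadigm
    truth: GroundTruth
    noise: NoiseModel

    def __post_init__(self) -> None:
        shapes = {e.shape for e in self.echoes}
        if len(shapes) != 1:
            raise ValueError("all echo arrays must share one shape")

    @property
    def n_volumes(self) -> int:
        return self.echoes[0].shape[-1]


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    d = sum(((idx[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3))
    return d <= 1.0


def generate_phantom(shape=(24, 24, 12), seed: int = 0,
                     config: PhantomConfig = PhantomConfig()) -> GroundTruth:
    """Build the deterministic head phantom for a given seed.

    The head is an inscribed ellipsoid; gray matter is the outer shell,
    white matter the core, and a small low-T2* pocket near the anterior
    inferior margin plays the role of an orbitofrontal dropout region. Gray
    matter is split into four quadrant ROIs (labels 1-4), each with its own
    task amplitude and hemodynamic lag.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < d for s, d in zip(shape, (16, 16, 8))):
        raise ValueError("phantom shape must be at least 16 x 16 x 8")
    rng = np.random.default_rng(seed)
    cx, cy, cz = [(s - 1) / 2 for s in shape]
    head = _ellipsoid(shape, (cx, cy, cz), (0.46 * shape[0], 0.46 * shape[1], 0.46 * shape[2]))
    core = _ellipsoid(shape, (cx, cy, cz), (0.28 * shape[0], 0.28 * shape[1], 0.30 * shape[2]))
    dropout = _ellipsoid(
        shape,
        (0.70 * shape[0], 0.5 * (shape[1] - 1), 0.30 * shape[2]),
        (0.10 * shape[0], 0.12 * shape[1], 0.14 * shape[2]),
    ) & head
    wm = core & ~dropout
    gm = head & ~core & ~dropout
    if not (gm.any() and wm.any() and dropout.any()):
        raise ValueError("shape too small to place all phantom compartments")

    # quadrant ROIs over GM
    labels = np.zeros(shape, dtype=np.int32)
    xg, yg = np.indices(shape)[:2]
    quad = (xg >= cx).astype(int) * 2 + (yg >= cy).astype(int)  # 0..3
    labels[gm] = quad[gm] + 1

    amps = np.asarray(config.roi_amplitudes, dtype=float) * config.amplitude_scale
    lags = np.asarray(config.roi_lags, dtype=float)
    if len(amps) < 4 or len(lags) < 4:
        raise ValueError("need at least 4 ROI amplitudes and lags")

    s0 = np.zeros(shape)
    s0[gm] = config.s0_gm
    s0[wm] = config.s0_wm
    s0[dropout] = config.s0_dropout
    s0[head] *= 1.0 + config.s0_texture_cv * rng.standard_normal(shape)[head]

    r2star0 = np.full(shape, 1000.0 / config.gm_t2star_ms)
    r2star0[wm] = 1000.0 / config.wm_t2star_ms
    r2star0[dropout] = 1000.0 / config.dropout_t2star_ms

    delta = np.zeros(shape)
    lag = np.zeros(shape)
    for roi in range(1, 5):
        m = labels == roi
        delta[m] = amps[roi - 1]
        lag[m] = lags[roi - 1]

    return GroundTruth(
        shape=shape, s0_map=s0, r2star0_map=r2star0, delta_r2star_map=delta,
        lag_map=lag, gm_mask=gm, wm_mask=wm, dropout_mask=dropout,
        head_mask=head, labels=labels,
    )


def simulate_session(
    truth: GroundTruth,
    paradigm: BHParadigm = BHParadigm(),
    params: SequenceParams | None = None,
    noise: NoiseModel = NoiseModel(),
    dt: float = 0.1,
) -> SyntheticSession:
    """Render the per-echo 4-D time series for one session."""
    from .theory import MBME_REFERENCE

    if params is None:
        params = MBME_REFERENCE
    if max(params.te_list) > 1000:
        raise ValueError("echo times look like seconds; expected milliseconds")

    n_vols = paradigm.n_volumes(params.tr)
    t_vols = np.arange(n_vols) * params.tr
    fine_t, x = convolved_response(paradigm, dt=dt, normalize=True)

    # voxelwise response sampled at volume times; piecewise-constant lags
    # let us evaluate one shifted response per unique lag
    nxyz = truth.shape
    resp = np.zeros(nxyz + (n_vols,))
    active = truth.delta_r2star_map > 0
    for lag_val in np.unique(truth.lag_map[active]) if active.any() else []:
        xs = np.interp(t_vols - lag_val, fine_t, x, left=0.0, right=0.0)
        m = active & (truth.lag_map == lag_val)
        resp[m] = xs

    r2 = truth.r2star0_map[..., None] - truth.delta_r2star_map[..., None] * resp

    tau = 2.0 * t_vols / t_vols[-1] - 1.0 if n_vols > 1 else np.zeros(1)
    mod = np.ones(n_vols)
    mod += noise.resp_amp * np.sin(2 * np.pi * noise.resp_freq * t_vols)
    for k, c in enumerate(noise.drift_coeffs, start=1):
        mod += c * tau**k

    rng = np.random.default_rng(noise.seed)
    echoes = []
    for te in params.te_list:
        clean = truth.s0_map[..., None] * np.exp(-te * r2 / 1000.0) * mod
        if noise.sigma_thermal > 0:
            clean = clean + noise.sigma_thermal * rng.standard_normal(clean.shape)
        echoes.append(clean)
    return SyntheticSession(
        echoes=tuple(echoes), params=params, paradigm=paradigm,
        truth=truth, noise=noise,
    )


def combined_truth_amplitude(session: SyntheticSession, echo_weight_maps) -> np.ndarray:
    """Closed-form peak response amplitude of a weighted echo combination.

    Given per-voxel combination weights (shape ``(n_echoes, x, y, z)``, e.g.
    from :func:`bhcvr.echo_combine.combination_weights`), returns the
    generator's noiseless signal at task peak (x = 1) minus baseline
    (x = 0) for each voxel — the ground truth a linear fit of the combined
    series should recover in the small-amplitude regime.
    """
    truth = session.truth
    w = np.asarray(echo_weight_maps)
    te = np.asarray(session.params.te_list).reshape((-1,) + (1,) * 3)
    base = truth.s0_map * np.exp(-te * truth.r2star0_map / 1000.0)
    peak = truth.s0_map * np.exp(
        -te * (truth.r2star0_map - truth.delta_r2star_map) / 1000.0
    )
    return (w * peak).sum(axis=0) - (w * base).sum(axis=0)


def _jitter_truth(truth: GroundTruth, cv: float, rng: np.random.Generator) -> GroundTruth:
    """Multiplicative lognormal perturbation of the task amplitude (mean 1)."""
    if cv == 0:
        return truth
    sigma = np.sqrt(np.log1p(cv**2))
    factor = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=truth.shape)
    delta = truth.delta_r2star_map * factor
    delta[~truth.gm_mask] = 0.0
    return replace(truth, delta_r2star_map=delta)


def simulate_retest(
    truth: GroundTruth,
    paradigm: BHParadigm = BHParadigm(),
    params: SequenceParams | None = None,
    noise: NoiseModel = NoiseModel(),
    jitter_cv: float = 0.0,
    seeds: tuple[int, int] = (0, 1),
) -> tuple[SyntheticSession, SyntheticSession]:
    """Simulate a test-retest session pair.

    Each session draws an independent multiplicative lognormal perturbation
    of the task amplitude map (coefficient of variation ``jitter_cv``;
    physiological day-to-day variability) and an independent thermal-noise
    realization. With ``jitter_cv = 0`` the two sessions share the truth
    exactly and differ only in noise; with zero noise as well they are
    bitwise identical.
    """
    if not (0 <= jitter_cv < 1):
        raise ValueError("jitter_cv must be in [0, 1)")
    sessions = []
    for s in seeds:
        rng = np.random.default_rng(s)
        t = _jitter_truth(truth, jitter_cv, rng)
        n = replace(noise, seed=int(rng.integers(0, 2**31 - 1)))
        sessions.append(simulate_session(t, paradigm, params, n))
    return sessions[0], sessions[1]
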