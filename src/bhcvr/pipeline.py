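"""End-to-end pipeline: simulate -> combine -> preprocess -> GLM/CVR -> retest.

Stages communicate through files (NIfTI / TSV / JSON) so any stage can be
re-run in isolation; every run echoes its resolved configuration and a
provenance log (package version, per-stage wall time, seeds) into the
output directory, making runs reconstructible from the outputs alone.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .echo_combine import combine_echoes, fit_t2star
from .glm import activation_mask, compute_cvr, compute_rcvr, fit_bh_glm
from .io import save_json, save_nifti
from .preprocess import (
    BoldSeries,
    compute_tsnr,
    discard_initial,
    gaussian_smooth,
    notch_filter_task,
    polynomial_nuisance,
)
from .repeatability import dice, wcv_and_diff
from .synthetic import NoiseModel, PhantomConfig, generate_phantom, simulate_retest
from .task_design import BHParadigm, build_regressor_set, default_lag_grid  # noqa: F401
from .theory import SequenceParams


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateConfig(_Strict):
    shape: tuple[int, int, int] = (24, 24, 12)
    seed: int = 0
    sigma_thermal: float = 3.0
    jitter_cv: float = 0.0
    amplitude_scale: float = 1.0


class AcquisitionConfig(_Strict):
    tr: float = 0.9
    te_list: tuple[float, ...] = (11.0, 30.0, 49.0)
    flip_angle: float = 60.0
    t1: float = 1.3


class PreprocessConfig(_Strict):
    n_discard: int = 10
    detrend_order: int = 3
    fwhm_mm: float = 0.0        # phantom ROIs are piecewise-constant; off by default
    voxel_size_mm: float = 3.0
    notch: bool = False
    notch_half_width: float = 0.005


class GLMConfig(_Strict):
    lags: tuple[float, ...] = default_lag_grid()
    p_threshold: float = 0.01
    ar1: bool = False


class PipelineConfig(_Strict):
    """Full run configuration; unknown keys are rejected at validation."""

    out_dir: str
    simulate: SimulateConfig = SimulateConfig()
    acquisition: AcquisitionConfig = AcquisitionConfig()
    preprocess: PreprocessConfig = PreprocessConfig()
    glm: GLMConfig = GLMConfig()
    retest: bool = True


def session_t2star_fit(session, n_discard: int = 10):
    """Per-voxel T2* fit from a session's post-discard echo means, exactly
    as :func:`analyze_session` computes it."""
    series = [
        discard_initial(BoldSeries(data=e, tr=session.params.tr), n_discard)
        for e in session.echoes
    ]
    return fit_t2star(
        np.stack([s.data.mean(axis=-1) for s in series]), session.params.te_list
    )


def analyze_session(
    session,
    n_discard: int = 10,
    detrend_order: int = 3,
    fwhm_mm: float = 0.0,
    voxel_size_mm: float = 3.0,
    notch: bool = False,
    lags=None,
    ar1: bool = False,
    p_threshold: float = 0.01,
):
    """In-memory single-session analysis: combine -> GLM -> CVR/rCVR.

    Returns ``(act, cvr, tsnr, active)``. Drift is fit jointly with the task
    regressor (see :func:`bhcvr.preprocess.polynomial_nuisance`).
    """
    if lags is None:
        lags = default_lag_grid()
    series_raw = [
        discard_initial(BoldSeries(data=e, tr=session.params.tr), n_discard)
        for e in session.echoes
    ]
    fit = fit_t2star(np.stack([s.data.mean(axis=-1) for s in series_raw]),
                     session.params.te_list)
    combined = BoldSeries(
        data=combine_echoes([s.data for s in series_raw], fit),
        tr=session.params.tr, n_discarded=n_discard,
    )
    if fwhm_mm > 0:
        combined = gaussian_smooth(combined, fwhm_mm, voxel_size_mm)
    tsnr = compute_tsnr(combined)
    mean_signal = combined.data.mean(axis=-1)
    if notch:
        combined = notch_filter_task(combined, f0=session.paradigm.task_frequency)

    regs = build_regressor_set(
        session.paradigm, tr=session.params.tr,
        n_vols=combined.n_t, n_discarded=n_discard, lags=lags,
    )
    act = fit_bh_glm(
        combined, regs,
        nuisance=polynomial_nuisance(combined.n_t, detrend_order),
        ar1=ar1, mask=session.truth.head_mask, mean_signal=mean_signal,
    )
    cvr = compute_cvr(act)
    cvr = compute_rcvr(cvr, session.truth.gm_mask)
    active = activation_mask(act, p_threshold)
    return act, cvr, tsnr, active


def _analyze_session(session, cfg: PipelineConfig, out: Path, tag: str) -> dict:
    pp = cfg.preprocess
    act, cvr, tsnr, active = analyze_session(
        session,
        n_discard=pp.n_discard, detrend_order=pp.detrend_order,
        fwhm_mm=pp.fwhm_mm, voxel_size_mm=pp.voxel_size_mm, notch=pp.notch,
        lags=cfg.glm.lags, ar1=cfg.glm.ar1, p_threshold=cfg.glm.p_threshold,
    )

    for name, arr in [
        ("beta", act.beta), ("tstat", act.tstat), ("zstat", act.zstat),
        ("lag", act.lag), ("cvr", cvr.cvr), ("rcvr", cvr.rcvr),
        ("tsnr", tsnr.tsnr), ("active_mask", active.astype(float)),
    ]:
        save_nifti(arr, out / f"{tag}_{name}.nii.gz", pp.voxel_size_mm)

    gm = session.truth.gm_mask
    return {
        "tag": tag,
        "dof": act.dof,
        "gm_mean_cvr": cvr.gm_mean_cvr,
        "gm_mean_tsnr": float(tsnr.tsnr[gm].mean()),
        "gm_mean_tsnr_norm": float(tsnr.tsnr_norm[gm].mean()),
        "n_active_voxels": int(active.sum()),
        "_active": active, "_rcvr": cvr.rcvr,
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured stages; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2) + "\n")

    log: list[dict] = []

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - annotate and re-raise
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    sim = config.simulate
    acq = config.acquisition
    params = SequenceParams(tr=acq.tr, te_list=acq.te_list,
                            flip_angle=acq.flip_angle, t1=acq.t1)
    paradigm = BHParadigm()

    def _simulate():
        truth = generate_phantom(sim.shape, seed=sim.seed,
                                 config=PhantomConfig(amplitude_scale=sim.amplitude_scale))
        noise = NoiseModel(sigma_thermal=sim.sigma_thermal)
        s1, s2 = simulate_retest(truth, paradigm, params, noise,
                                 jitter_cv=sim.jitter_cv,
                                 seeds=(sim.seed, sim.seed + 1))
        for tag, s in (("ses1", s1), ("ses2", s2)):
            for i, e in enumerate(s.echoes):
                save_nifti(e, out / f"{tag}_echo{i + 1}.nii.gz")
        save_nifti(truth.labels, out / "labels.nii.gz")
        save_nifti(truth.gm_mask.astype(float), out / "gm_mask.nii.gz")
        return s1, s2

    s1, s2 = stage("simulate", _simulate)
    r1 = stage("analyze_ses1", lambda: _analyze_session(s1, config, out, "ses1"))
    summary = {"version": __version__, "sessions": [
        {k: v for k, v in r1.items() if not k.startswith("_")}
    ]}

    if config.retest:
        r2 = stage("analyze_ses2", lambda: _analyze_session(s2, config, out, "ses2"))
        summary["sessions"].append({k: v for k, v in r2.items() if not k.startswith("_")})

        def _retest():
            gm = s1.truth.gm_mask
            dc = dice(r1["_active"] & gm, r2["_active"] & gm)
            metrics = wcv_and_diff(r1["_rcvr"], r2["_rcvr"], gm)
            return {
                "dice": dc,
                "gm_mean_rcvr_diff": metrics.gm_mean_diff,
                "gm_mean_wcv": metrics.gm_mean_wcv,
            }

        summary["retest"] = stage("retest", _retest)

    summary["stages"] = log
    save_json(summary, out / "summary.json")
    return out
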