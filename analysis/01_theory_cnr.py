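#!/usr/bin/env python
"""Acquisition theory: what does a longer-TR three-echo protocol buy?

Evaluates the steady-state signal ratio between the two repetition times,
the Ernst angles, and the CNR of the T2*-weighted echo combination versus
the single middle echo across a T2* sweep. Writes the sweep table to
results/theory_cnr_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from bhcvr.theory import (
    MB_REFERENCE,
    MBME_REFERENCE,
    cnr_ratio,
    cnr_sweep,
    ernst_angle,
    steady_state_signal,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    ss_mbme = steady_state_signal(MBME_REFERENCE)
    ss_mb = steady_state_signal(MB_REFERENCE)
    print(f"steady-state signal: multi-echo (TR 0.9 s) {ss_mbme:.4f}, "
          f"single-echo (TR 0.65 s) {ss_mb:.4f}, ratio {ss_mbme / ss_mb:.3f}")
    print(f"Ernst angles: TR 0.65 s -> {ernst_angle(0.65, 1.3):.1f} deg, "
          f"TR 0.90 s -> {ernst_angle(0.9, 1.3):.1f} deg "
          "(both protocols use 60 deg)")

    ratio_50 = cnr_ratio(MBME_REFERENCE, MB_REFERENCE, 50.0)
    print(f"CNR ratio (3-echo combination vs TE=30 ms) at T2* = 50 ms, "
          f"steady-state factor included: {ratio_50:.3f}")

    grid = np.arange(10.0, 121.0, 1.0)
    sweep = pd.DataFrame(cnr_sweep(MBME_REFERENCE, MB_REFERENCE, grid))
    sweep.to_csv(RESULTS / "theory_cnr_sweep.csv", index=False)
    above25 = sweep[sweep.t2star_ms >= 25]
    monotone = bool(np.all(np.diff(above25.ratio) > 0))
    print(f"CNR ratio rises monotonically with T2* above 25 ms: {monotone}")
    print(f"wrote {RESULTS / 'theory_cnr_sweep.csv'} ({len(sweep)} rows)")


if __name__ == "__main__":
    main()
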