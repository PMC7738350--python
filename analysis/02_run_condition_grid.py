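#!/usr/bin/env python
"""Run the full 72-cell condition grid at the reduced study scale.

Crosses model (DINA, RRUM, CRUM) x bank quality (high, low, mix) x
calibration-error SD (0, 0.1, 0.2, 0.3) x termination threshold (0.7, 0.8),
500 examinees and 10 replications per cell, thresholds paired within
replication.  Writes one summary row per cell to results/grid_summary.csv.
"""

import logging
import time
from pathlib import Path

from cdcat import run_grid

logging.basicConfig(level=logging.INFO, format="%(message)s")

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

t0 = time.time()
grid = run_grid(n_examinees=500, n_replications=10, master_seed=20260923)
grid.to_csv(OUT / "grid_summary.csv", index=False)
print(f"\nwrote {len(grid)} condition summaries to {OUT/'grid_summary.csv'} "
      f"in {time.time()-t0:.0f}s")

for model in ("DINA", "RRUM", "CRUM"):
    sub = grid[(grid.model == model) & (grid.quality == "low") & (grid.epsilon == 0.7)]
    line = ", ".join(f"sd={r.error_sd:.1f}: PCR={r.pcr_mean:.3f} ATL={r.atl_mean:.1f} RTE={r.rte_mean:.2f}"
                     for r in sub.itertuples())
    print(f"{model} low quality, eps=0.7 -> {line}")
print("\nReading: for DINA and RRUM, accuracy and test length fall and RTE rises "
      "with calibration error; CRUM is nearly flat — the additive logit "
      "parameterization lets over- and under-estimated effects cancel.")
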