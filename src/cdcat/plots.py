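"""Panel plots of the grid results: classification accuracy, test length and
relative measurement precision as functions of the calibration-error SD, one
panel per (model, quality) combination, one line per termination threshold."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def _panel_grid(results: pd.DataFrame, metric: str, ylabel: str, path: Path) -> None:
    models = sorted(results["model"].unique(), key=str)
    qualities = [q for q in ("high", "low", "mix") if q in set(results["quality"])]
    fig, axes = plt.subplots(
        len(models), len(qualities),
        figsize=(3.2 * len(qualities), 2.6 * len(models)),
        sharex=True, squeeze=False,
    )
    for r, model in enumerate(models):
        for c, quality in enumerate(qualities):
            ax = axes[r][c]
            cell = results[(results["model"] == model) & (results["quality"] == quality)]
            for eps, sub in cell.groupby("epsilon"):
                sub = sub.sort_values("error_sd")
                ax.errorbar(
                    sub["error_sd"], sub[f"{metric}_mean"], yerr=sub[f"{metric}_sd"],
                    marker="o", capsize=2, label=f"eps={eps}",
                )
            ax.set_title(f"{model} / {quality}", fontsize=9)
            if c == 0:
                ax.set_ylabel(ylabel, fontsize=8)
            if r == len(models) - 1:
                ax.set_xlabel("calibration-error SD", fontsize=8)
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def report_figures(results: pd.DataFrame, outdir: str | Path) -> list[Path]:
    """Write the four standard panel figures; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for metric, ylabel, name in [
        ("pcr", "pattern correct rate", "pcr.png"),
        ("aacr", "attribute correct rate", "aacr.png"),
        ("atl", "average test length", "atl.png"),
        ("rmp", "relative measurement precision", "rmp.png"),
    ]:
        path = outdir / name
        _panel_grid(results, metric, ylabel, path)
        written.append(path)
    return written
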