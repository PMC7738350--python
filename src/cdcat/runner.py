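"""Orchestration of the simulation grid.

The full design crosses model (DINA, RRUM, CRUM) x bank quality (high, low,
mix) x calibration-error SD (0, 0.1, 0.2, 0.3) x termination threshold
(0.7, 0.8) — 72 cells — with replications per cell.  The threshold is a
within-group factor: both thresholds are evaluated on sessions grown from
identical seeds, so their lengths are paired per examinee.

Seeding
-------
Every random stream derives purely from ``(master_seed, purpose, condition
labels, replication index)`` via :class:`numpy.random.SeedSequence` — no
global state, so results are independent of execution order and safe to
parallelize.  Within a replication index, the true bank (per model/quality)
and the examinees and response variates (shared by all cells) are reused
across error levels and thresholds, isolating the calibration-error effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bank import (
    DEFAULT_CLIP,
    QUALITY_LEVELS,
    build_q_matrix,
    generate_examinees,
    inject_calibration_error,
    sample_true_bank,
)
from .cdm import MODELS, class_prob_table, latent_classes
from .engine import TerminationRule, kl_matrices, run_sessions_batch
from .metrics import aacr, cdi_items, pcr, rmp, rte

log = logging.getLogger("cdcat")

DEFAULT_ERROR_SDS = (0.0, 0.1, 0.2, 0.3)
DEFAULT_EPSILONS = (0.7, 0.8)

# purpose codes for seed substreams
_STREAM_BANK, _STREAM_ERROR, _STREAM_EXAMINEES, _STREAM_RESPONSES = 1, 2, 3, 4

METRIC_NAMES = ("pcr", "aacr", "atl", "rmp", "rte")


@dataclass(frozen=True)
class ConditionSpec:
    """One design cell plus the scale and seeding knobs."""

    model: str
    quality: str
    error_sd: float
    epsilon: float
    n_examinees: int = 2000
    n_replications: int = 25
    max_length: int = 30
    K: int = 5
    master_seed: int = 0
    clip: tuple[float, float] = DEFAULT_CLIP
    cdi_weighting: str = "inv_hamming"

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.quality not in QUALITY_LEVELS:
            raise ValueError(f"unknown quality {self.quality!r}")
        if self.error_sd < 0:
            raise ValueError("error_sd must be >= 0")


def substream(master_seed: int, *codes: int) -> np.random.Generator:
    """Independent generator keyed by integer labels (pure, order-free)."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), *map(int, codes)]))


def _codes(model: str, quality: str, error_sd: float) -> tuple[int, int, int]:
    return MODELS.index(model), QUALITY_LEVELS.index(quality), int(round(error_sd * 10))


def run_replication(
    spec: ConditionSpec,
    rep: int,
    *,
    epsilons: tuple[float, ...] | None = None,
    q: np.ndarray | None = None,
) -> dict[float, dict[str, float]]:
    """Run one replication of a cell; returns {epsilon: metric dict}.

    A replication draws a fresh true bank, injects calibration error, draws
    fresh examinees and one uniform variate per potential item, then runs
    every requested threshold on those same variates.
    """
    if epsilons is None:
        epsilons = (spec.epsilon,)
    if q is None:
        q = build_q_matrix(spec.K)
    m, ql, sd10 = _codes(spec.model, spec.quality, spec.error_sd)

    true_bank = sample_true_bank(
        spec.model, spec.quality, q, substream(spec.master_seed, _STREAM_BANK, m, ql, rep)
    )
    est_bank = inject_calibration_error(
        true_bank,
        spec.error_sd,
        substream(spec.master_seed, _STREAM_ERROR, m, ql, sd10, rep),
        clip=spec.clip,
    )
    profiles = generate_examinees(
        spec.n_examinees, spec.K, substream(spec.master_seed, _STREAM_EXAMINEES, rep)
    )
    uniforms = substream(spec.master_seed, _STREAM_RESPONSES, rep).random(
        (spec.n_examinees, spec.max_length)
    )

    true_table = class_prob_table(true_bank)
    est_table = class_prob_table(est_bank)
    A = kl_matrices(est_table)
    cdi_est = cdi_items(est_table, weighting=spec.cdi_weighting, A=A)
    cdi_true = cdi_items(true_table, weighting=spec.cdi_weighting)
    classes = latent_classes(spec.K)

    out: dict[float, dict[str, float]] = {}
    for eps in epsilons:
        batch = run_sessions_batch(
            profiles,
            true_bank,
            est_bank,
            TerminationRule(epsilon=eps, max_length=spec.max_length),
            uniforms,
            tables=(true_table, est_table),
            A=A,
        )
        estimates = classes[batch.map_class]
        out[eps] = {
            "pcr": pcr(estimates, profiles),
            "aacr": aacr(estimates, profiles),
            "atl": float(batch.lengths.mean()),
            "rmp": rmp(batch),
            "rte": rte(batch, true_bank, est_bank, cdi_true=cdi_true, cdi_est=cdi_est),
        }
    return out


def _summarize(spec: ConditionSpec, per_rep: list[dict[str, float]]) -> dict[str, float]:
    row: dict[str, float] = {
        "model": spec.model,
        "quality": spec.quality,
        "error_sd": spec.error_sd,
        "epsilon": spec.epsilon,
        "n_replications": len(per_rep),
        "n_examinees": spec.n_examinees,
    }
    for name in METRIC_NAMES:
        vals = np.array([r[name] for r in per_rep])
        row[f"{name}_mean"] = float(vals.mean())
        row[f"{name}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return row


def run_condition(spec: ConditionSpec, q: np.ndarray | None = None) -> dict[str, float]:
    """Replicate one cell and aggregate each metric's mean and SD over replications."""
    if q is None:
        q = build_q_matrix(spec.K)
    per_rep = []
    for rep in range(spec.n_replications):
        res = run_replication(spec, rep, q=q)[spec.epsilon]
        log.info(
            "%s/%s sd=%.1f eps=%.1f rep %d: %s",
            spec.model, spec.quality, spec.error_sd, spec.epsilon, rep,
            " ".join(f"{k}={v:.4g}" for k, v in res.items()),
        )
        per_rep.append(res)
    return _summarize(spec, per_rep)


def run_grid(
    *,
    models: tuple[str, ...] = MODELS,
    qualities: tuple[str, ...] = QUALITY_LEVELS,
    error_sds: tuple[float, ...] = DEFAULT_ERROR_SDS,
    epsilons: tuple[float, ...] = DEFAULT_EPSILONS,
    n_examinees: int = 2000,
    n_replications: int = 25,
    max_length: int = 30,
    K: int = 5,
    master_seed: int = 0,
    clip: tuple[float, float] = DEFAULT_CLIP,
    cdi_weighting: str = "inv_hamming",
) -> pd.DataFrame:
    """Run the full condition grid; one summary row per (cell, epsilon).

    The default grid is 3 models x 3 qualities x 4 error SDs x 2 thresholds
    = 72 rows.  Thresholds are evaluated within-replication on shared
    variates; sharing of banks/examinees across cells follows from the
    label-keyed seeds, not from loop structure.
    """
    q = build_q_matrix(K)
    rows = []
    for model in models:
        for quality in qualities:
            for sd in error_sds:
                base = ConditionSpec(
                    model=model, quality=quality, error_sd=sd, epsilon=epsilons[0],
                    n_examinees=n_examinees, n_replications=n_replications,
                    max_length=max_length, K=K, master_seed=master_seed,
                    clip=clip, cdi_weighting=cdi_weighting,
                )
                per_eps: dict[float, list[dict[str, float]]] = {e: [] for e in epsilons}
                for rep in range(n_replications):
                    res = run_replication(base, rep, epsilons=tuple(epsilons), q=q)
                    for e in epsilons:
                        per_eps[e].append(res[e])
                for e in epsilons:
                    rows.append(_summarize(replace(base, epsilon=e), per_eps[e]))
                log.info("finished cell %s/%s sd=%.1f", model, quality, sd)
    return pd.DataFrame(rows)


def rte_table(results: pd.DataFrame) -> pd.DataFrame:
    """Pivot the grid results into the RTE summary layout: one row per
    (model, quality, nonzero error SD), mean and SD columns per threshold."""
    sub = results[results["error_sd"] > 0]
    wide = sub.pivot_table(
        index=["model", "quality", "error_sd"],
        columns="epsilon",
        values=["rte_mean", "rte_sd"],
    )
    wide.columns = [f"{'M' if v == 'rte_mean' else 'SD'}_eps{e}" for v, e in wide.columns]
    return wide.reset_index()
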