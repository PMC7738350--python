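"""Synthetic item banks, examinees and responses.

This module is the data-generating stage of the simulation: it constructs the
300-item, 5-attribute Q-matrix from three basic blocks, samples true item
parameters uniformly within quality-stratified ranges, forms "calibrated"
banks by adding zero-mean Gaussian noise to the true parameters, and draws
examinee attribute profiles and item responses.

Quality ranges
--------------
Three bank-quality levels (``high``, ``low``, ``mix``) set the uniform
sampling ranges per model.  High-quality items discriminate strongly (small
DINA s/g; RRUM baseline near 1 with strong penalties; CRUM with low intercept
and near-certain full-mastery success); low-quality items are noisier; ``mix``
spans the union of both ranges.

Calibration error
-----------------
Operational banks never hold the true parameters: calibration from a finite
examinee sample leaves residual error.  That error is modeled directly as
additive N(0, sd) noise, sd in {0, 0.1, 0.2, 0.3}, applied on each
parameter's native scale — the probability scale for DINA s/g and RRUM
pi*/r*, the logit scale for CRUM deltas.  Perturbed probability-scale
parameters are clipped to [0.01, 0.99] to keep likelihoods finite; no
monotonicity repair is applied (the perturbed bank is operational "as
calibrated", defects included).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import expit, logit

from .cdm import ItemBank, class_prob_table, validate_q_matrix

#: Uniform sampling ranges per (model, quality): parameter -> (low, high).
#: CRUM is parameterized by its intercept delta0 and the implied full-mastery
#: success probability ``p_plus``; main effects are solved from the two.
QUALITY_RANGES: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "DINA": {
        "high": {"s": (0.05, 0.25), "g": (0.05, 0.25)},
        "low": {"s": (0.25, 0.45), "g": (0.25, 0.45)},
        "mix": {"s": (0.05, 0.45), "g": (0.05, 0.45)},
    },
    "RRUM": {
        "high": {"pi_star": (0.75, 0.95), "r_star": (0.05, 0.40)},
        "low": {"pi_star": (0.55, 0.75), "r_star": (0.15, 0.50)},
        "mix": {"pi_star": (0.55, 0.95), "r_star": (0.05, 0.50)},
    },
    "CRUM": {
        "high": {"delta0": (-3.0, -1.1), "p_plus": (0.85, 1.0)},
        "low": {"delta0": (-1.1, -0.2), "p_plus": (0.6, 0.85)},
        "mix": {"delta0": (-3.0, -0.2), "p_plus": (0.6, 1.0)},
    },
}

QUALITY_LEVELS = ("high", "low", "mix")

#: Default clip interval for perturbed probability-scale parameters.
DEFAULT_CLIP = (0.01, 0.99)


# ---------------------------------------------------------------------------
# Q-matrix construction
# ---------------------------------------------------------------------------

def build_q_matrix(K: int = 5, block_multipliers: tuple[int, int, int] = (20, 14, 6)) -> np.ndarray:
    """Build the item bank's Q-matrix from three basic blocks.

    Block Q1 holds the K single-attribute rows (the identity), Q2 all
    C(K, 2) two-attribute rows, Q3 all C(K, 3) three-attribute rows; the bank
    stacks ``block_multipliers`` = (20, 14, 6) copies of each.  With K = 5
    this yields 20*5 + 14*10 + 6*10 = 300 items, the only block composition
    consistent with that bank size.  Deterministic — no RNG involved.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    m1, m2, m3 = block_multipliers
    blocks = []
    q1 = np.eye(K, dtype=np.int8)
    blocks.append(np.tile(q1, (m1, 1)))
    if K >= 2 and m2 > 0:
        q2 = np.zeros((len(list(combinations(range(K), 2))), K), dtype=np.int8)
        for i, pair in enumerate(combinations(range(K), 2)):
            q2[i, list(pair)] = 1
        blocks.append(np.tile(q2, (m2, 1)))
    if K >= 3 and m3 > 0:
        q3 = np.zeros((len(list(combinations(range(K), 3))), K), dtype=np.int8)
        for i, triple in enumerate(combinations(range(K), 3)):
            q3[i, list(triple)] = 1
        blocks.append(np.tile(q3, (m3, 1)))
    return validate_q_matrix(np.vstack(blocks))


# ---------------------------------------------------------------------------
# True-bank sampling
# ---------------------------------------------------------------------------

def sample_true_bank(
    model: str,
    quality: str,
    q: np.ndarray,
    rng: np.random.Generator,
    *,
    crum_split: str = "dirichlet",
) -> ItemBank:
    """Sample a true item bank with parameters uniform in the quality ranges.

    DINA draws s_j, g_j; RRUM draws pi*_j and one r*_jk per required
    attribute.  CRUM draws the intercept delta0_j and a full-mastery target
    probability p+_j, then solves sum_k delta_jk = logit(p+_j) - delta0_j and
    splits the gap across the item's required attributes — by uniform random
    proportions (``crum_split="dirichlet"``, the default, avoiding artificial
    symmetry) or equally (``"equal"``).  Main effects must be positive
    (mastery cannot hurt); p+_j is redrawn in the rare case a non-default
    range makes the gap non-positive.
    """
    q = validate_q_matrix(q)
    J, K = q.shape
    try:
        ranges = QUALITY_RANGES[model][quality]
    except KeyError:
        raise ValueError(f"no quality ranges defined for model={model!r}, quality={quality!r}") from None
    for lo, hi in ranges.values():
        if not hi > lo:
            raise ValueError(f"empty quality range ({lo}, {hi}) for {model}/{quality}")
    req = q.astype(bool)

    if model == "DINA":
        params = {
            "s": rng.uniform(*ranges["s"], size=J),
            "g": rng.uniform(*ranges["g"], size=J),
        }
    elif model == "RRUM":
        r = np.full((J, K), np.nan)
        r[req] = rng.uniform(*ranges["r_star"], size=int(req.sum()))
        params = {"pi_star": rng.uniform(*ranges["pi_star"], size=J), "r_star": r}
    elif model == "CRUM":
        delta0 = rng.uniform(*ranges["delta0"], size=J)
        p_plus = rng.uniform(*ranges["p_plus"], size=J)
        # guard against a literal draw of 1.0 (logit would be infinite)
        p_plus = np.minimum(p_plus, 1.0 - 1e-12)
        gap = logit(p_plus) - delta0
        for _ in range(100):
            bad = gap <= 0
            if not bad.any():
                break
            p_plus[bad] = np.minimum(rng.uniform(*ranges["p_plus"], size=int(bad.sum())), 1.0 - 1e-12)
            gap = logit(p_plus) - delta0
        else:
            raise ValueError("could not draw positive CRUM main-effect totals; check ranges")
        delta = np.full((J, K), np.nan)
        for j in range(J):
            k_req = np.flatnonzero(req[j])
            if crum_split == "equal":
                props = np.full(k_req.size, 1.0 / k_req.size)
            else:
                props = rng.dirichlet(np.ones(k_req.size))
            delta[j, k_req] = gap[j] * props
        params = {"delta0": delta0, "delta": delta}
    else:
        raise ValueError(f"unknown model {model!r}")
    return ItemBank(model=model, q=q, params=params, quality=quality)


# ---------------------------------------------------------------------------
# Calibration error
# ---------------------------------------------------------------------------

def inject_calibration_error(
    bank: ItemBank,
    sd: float,
    rng: np.random.Generator,
    clip: tuple[float, float] = DEFAULT_CLIP,
) -> ItemBank:
    """Return a "calibrated" bank: every free parameter plus N(0, sd) noise.

    Noise is independent per parameter and added on the parameter's native
    scale; probability-scale parameters are then clipped to ``clip``
    (default [0.01, 0.99]).  ``sd = 0`` reproduces the true bank exactly.
    """
    if sd < 0:
        raise ValueError("calibration-error sd must be >= 0")
    lo, hi = clip
    req = bank.q.astype(bool)
    p = bank.params

    def perturb_prob(arr: np.ndarray) -> np.ndarray:
        return np.clip(arr + rng.normal(0.0, sd, size=arr.shape), lo, hi)

    if bank.model == "DINA":
        new = {"s": perturb_prob(p["s"]), "g": perturb_prob(p["g"])}
    elif bank.model == "RRUM":
        r = p["r_star"].copy()
        r[req] = np.clip(r[req] + rng.normal(0.0, sd, size=int(req.sum())), lo, hi)
        new = {"pi_star": perturb_prob(p["pi_star"]), "r_star": r}
    else:  # CRUM: logit scale, unbounded, no clipping
        d = p["delta"].copy()
        d[req] = d[req] + rng.normal(0.0, sd, size=int(req.sum()))
        new = {"delta0": p["delta0"] + rng.normal(0.0, sd, size=bank.n_items), "delta": d}
    return ItemBank(model=bank.model, q=bank.q, params=new, quality=bank.quality)


# ---------------------------------------------------------------------------
# Examinees and responses
# ---------------------------------------------------------------------------

def generate_examinees(
    N: int, K: int, rng: np.random.Generator, p_mastery: float = 0.5
) -> np.ndarray:
    """N x K binary matrix of true attribute profiles, i.i.d. Bernoulli(p_mastery)."""
    if N <= 0:
        raise ValueError("N must be > 0")
    return (rng.random((N, K)) < p_mastery).astype(np.int8)


def simulate_response(
    profile: np.ndarray,
    item: int,
    true_bank: ItemBank,
    rng: np.random.Generator,
    _table: np.ndarray | None = None,
) -> int:
    """Bernoulli response draw for one (examinee, item) under the TRUE bank.

    Responses always come from the unperturbed parameters: the calibrated
    bank only drives selection and scoring, never the data.
    """
    from .cdm import class_index

    table = class_prob_table(true_bank) if _table is None else _table
    prob = table[class_index(profile), item]
    return int(rng.random() < prob)
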