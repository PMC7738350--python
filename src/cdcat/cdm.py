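"""Cognitive diagnosis models: item response functions and latent-class machinery.

Three models are supported, all defined over a binary attribute profile
``alpha`` of length K and a Q-matrix row ``q`` declaring which attributes an
item requires:

* **DINA** (deterministic input, noisy "and" gate) — conjunctive: the ideal
  response eta = prod_k alpha_k^q_k is 1 only under full mastery of the
  required attributes; P(Y=1) = (1-s)^eta * g^(1-eta) with slipping s and
  guessing g.
* **RRUM** (reduced reparameterized unified model) — non-compensatory
  multiplicative: P(Y=1) = pi* * prod_k r*_k^((1-alpha_k) q_k); the baseline
  pi* is the full-mastery success probability, each missing required
  attribute multiplies in a penalty r* in (0,1).
* **CRUM** (compensatory reparameterized unified model) — additive on the
  logit scale: logit P(Y=1) = delta0 + sum_k delta_k alpha_k q_k.

Latent classes
--------------
The 2^K attribute profiles are enumerated by binary counting with attribute 1
as the least-significant bit: class index c has alpha_k = (c >> k) & 1 for
k = 0..K-1 (0-based). This ordering is fixed so posterior vectors are
comparable across runs and implementations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit

MODELS = ("DINA", "RRUM", "CRUM")


# ---------------------------------------------------------------------------
# Q-matrix and item bank containers
# ---------------------------------------------------------------------------

def validate_q_matrix(q: np.ndarray) -> np.ndarray:
    """Validate and return a J x K binary Q-matrix as an int array.

    Every entry must be 0 or 1 and every item (row) must require at least one
    attribute.
    """
    q = np.asarray(q)
    if q.ndim != 2:
        raise ValueError(f"Q-matrix must be 2-D, got shape {q.shape}")
    if not np.isin(q, (0, 1)).all():
        raise ValueError("Q-matrix entries must be exactly 0 or 1")
    q = q.astype(np.int8)
    if (q.sum(axis=1) == 0).any():
        raise ValueError("every Q-matrix row must have at least one 1")
    return q


@dataclass
class ItemBank:
    """A model tag, a Q-matrix and per-item parameters.

    ``params`` holds model-specific numpy arrays:

    * DINA: ``s`` (J,), ``g`` (J,) — slipping and guessing, in (0, 1)
    * RRUM: ``pi_star`` (J,), ``r_star`` (J, K) with NaN where q_jk = 0
    * CRUM: ``delta0`` (J,), ``delta`` (J, K) with NaN where q_jk = 0

    The same container holds a *true* bank and its *calibrated*
    (error-affected) counterpart; only the parameter values differ.
    """

    model: str
    q: np.ndarray
    params: dict[str, np.ndarray]
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {MODELS}")
        self.q = validate_q_matrix(self.q)
        J, K = self.q.shape
        req = self.q.astype(bool)
        p = self.params
        if self.model == "DINA":
            for name in ("s", "g"):
                arr = np.asarray(p[name], dtype=float)
                if arr.shape != (J,):
                    raise ValueError(f"DINA param {name!r} must have shape ({J},)")
                if not ((arr > 0) & (arr < 1)).all():
                    raise ValueError(f"DINA param {name!r} must lie strictly in (0, 1)")
                p[name] = arr
        elif self.model == "RRUM":
            pi = np.asarray(p["pi_star"], dtype=float)
            r = np.asarray(p["r_star"], dtype=float)
            if pi.shape != (J,) or r.shape != (J, K):
                raise ValueError("RRUM params must be pi_star (J,) and r_star (J, K)")
            if not ((pi > 0) & (pi < 1)).all():
                raise ValueError("pi_star must lie strictly in (0, 1)")
            if not ((r[req] > 0) & (r[req] < 1)).all():
                raise ValueError("r_star must lie strictly in (0, 1) where q_jk = 1")
            r = r.copy()
            r[~req] = np.nan
            p["pi_star"], p["r_star"] = pi, r
        else:  # CRUM
            d0 = np.asarray(p["delta0"], dtype=float)
            d = np.asarray(p["delta"], dtype=float)
            if d0.shape != (J,) or d.shape != (J, K):
                raise ValueError("CRUM params must be delta0 (J,) and delta (J, K)")
            if not np.isfinite(d0).all() or not np.isfinite(d[req]).all():
                raise ValueError("CRUM parameters must be finite")
            d = d.copy()
            d[~req] = np.nan
            p["delta0"], p["delta"] = d0, d

    @property
    def n_items(self) -> int:
        return self.q.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.q.shape[1]


# ---------------------------------------------------------------------------
# Latent class space
# ---------------------------------------------------------------------------

def latent_classes(K: int) -> np.ndarray:
    """All 2^K attribute profiles as a (2^K, K) binary matrix.

    Row c is the profile of class c under the binary-counting convention
    (attribute 1 = least-significant bit), i.e. ``classes[c, k] = (c >> k) & 1``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    c = np.arange(2**K)
    return ((c[:, None] >> np.arange(K)[None, :]) & 1).astype(np.int8)


def class_index(profile: np.ndarray) -> int:
    """Inverse of :func:`latent_classes`: map a profile to its class index."""
    profile = np.asarray(profile)
    return int(profile @ (1 << np.arange(profile.shape[-1])))


# ---------------------------------------------------------------------------
# Scalar item response functions
# ---------------------------------------------------------------------------

def ideal_response(alpha, q_row) -> int:
    """DINA ideal response eta = prod_k alpha_k^q_jk.

    1 iff every attribute the item requires is mastered.
    """
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError(f"profile length {alpha.shape} != q-row length {q_row.shape}")
    return int(np.all(alpha >= q_row))


def prob_dina(alpha, q_row, s: float, g: float) -> float:
    """P(Y=1 | alpha) under DINA: 1-s under full required mastery, else g."""
    eta = ideal_response(alpha, q_row)
    return (1.0 - s) if eta else g


def prob_rrum(alpha, q_row, pi_star: float, r_star) -> float:
    """P(Y=1 | alpha) under RRUM: pi* times r*_k for each missing required attribute.

    ``r_star`` is a length-K vector; entries where q_jk = 0 are ignored (may
    be NaN).
    """
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError("profile/q-row length mismatch")
    r = np.asarray(r_star, dtype=float)
    missing = (q_row == 1) & (alpha == 0)
    return float(pi_star * np.prod(r[missing])) if missing.any() else float(pi_star)


def prob_crum(alpha, q_row, delta0: float, delta) -> float:
    """P(Y=1 | alpha) under CRUM: logistic(delta0 + sum_k delta_k alpha_k q_jk)."""
    alpha = np.asarray(alpha)
    q_row = np.asarray(q_row)
    if alpha.shape != q_row.shape:
        raise ValueError("profile/q-row length mismatch")
    d = np.asarray(delta, dtype=float)
    active = (q_row == 1) & (alpha == 1)
    return float(expit(delta0 + d[active].sum()))


# ---------------------------------------------------------------------------
# Class probability table
# ---------------------------------------------------------------------------

def class_prob_table(bank: ItemBank) -> np.ndarray:
    """P(Y_j = 1 | alpha_c) for every latent class c and item j.

    Returns a (2^K, J) matrix laid out in the :func:`latent_classes` ordering.
    This table is the central computational cache: the response generator,
    the posterior update, the MPWKL index and the CDI all read from it.
    """
    q = bank.q
    J, K = q.shape
    classes = latent_classes(K)  # (C, K)
    p = bank.params
    if bank.model == "DINA":
        # eta[c, j] = 1 iff class c masters all attributes item j requires
        eta = (classes @ q.T) == q.sum(axis=1)[None, :]
        table = np.where(eta, 1.0 - p["s"][None, :], p["g"][None, :])
    elif bank.model == "RRUM":
        log_r = np.where(q.astype(bool), np.log(p["r_star"]), 0.0)  # (J, K)
        # sum over missing required attributes of log r*
        log_pen = (1 - classes) @ log_r.T  # (C, J)
        table = p["pi_star"][None, :] * np.exp(log_pen)
    elif bank.model == "CRUM":
        d = np.where(q.astype(bool), p["delta"], 0.0)  # (J, K)
        logits = p["delta0"][None, :] + classes @ d.T
        table = expit(logits)
    else:  # pragma: no cover - guarded by ItemBank
        raise ValueError(f"unknown model {bank.model!r}")
    return table
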