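"""The variable-length adaptive loop: posterior updating, MPWKL selection,
threshold termination, MAP classification.

The engine never sees true parameters.  It selects items, updates the
posterior over the 2^K latent classes and decides termination using the
*calibrated* (possibly error-affected) bank; responses are generated outside
from the true bank.  This asymmetry is the whole point of the study design —
a miscalibrated bank can produce spuriously confident posteriors and end the
test early.

Item selection uses the modified posterior-weighted Kullback-Leibler (MPWKL)
index: the double posterior-weighted sum, over ordered latent-class pairs
(d, c), of the KL divergence between the item's Bernoulli response
distributions under class d and class c,

    MPWKL_j = sum_d sum_c KL( P_j(.|alpha_d) || P_j(.|alpha_c) )
                      * pi(alpha_d | Y) * pi(alpha_c | Y)
            = pi^T A_j pi,   A_j[d, c] = KL_j(d, c),

with natural logarithms.  The item with the largest index is administered;
ties break to the lowest item index.  The test stops at the first step where
the maximum posterior probability reaches the threshold epsilon, or at the
maximum length (30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cdm import ItemBank, class_prob_table

#: probability clip used only inside KL computations so every term is finite;
#: operational parameter clipping happens in the bank generator.
_KL_EPS = 1e-12


# ---------------------------------------------------------------------------
# Posterior state
# ---------------------------------------------------------------------------

@dataclass
class PosteriorState:
    """Posterior pi(alpha_c | Y) over latent classes plus administration history."""

    pi: np.ndarray
    administered: list[int] = field(default_factory=list)
    responses: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if (self.pi < 0).any() or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("posterior must be a probability vector")
        if len(set(self.administered)) != len(self.administered):
            raise ValueError("administered items must be distinct")


@dataclass(frozen=True)
class TerminationRule:
    """Stop when max-class posterior >= epsilon, or at max_length items."""

    epsilon: float = 0.7
    max_length: int = 30

    def __post_init__(self) -> None:
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.max_length < 1:
            raise ValueError("max_length must be >= 1")


@dataclass
class SessionRecord:
    """Outcome of one adaptive session."""

    examinee: int
    administered: list[int]
    responses: list[int]
    posterior: np.ndarray
    map_class: int
    map_estimate: np.ndarray
    test_length: int
    terminated_by: str  # 'threshold' | 'max_length'


def init_posterior(K: int) -> PosteriorState:
    """Uniform prior over the 2^K classes — the Bernoulli(0.5) generating prior."""
    if K < 1:
        raise ValueError("K must be >= 1")
    C = 2**K
    return PosteriorState(pi=np.full(C, 1.0 / C))


def update_posterior(
    state: PosteriorState, item: int, response: int, table: np.ndarray
) -> PosteriorState:
    """Bayes update: pi'_c proportional to pi_c * p_cj^x (1-p_cj)^(1-x)."""
    if item in state.administered:
        raise ValueError(f"item {item} already administered")
    if response not in (0, 1):
        raise ValueError("response must be 0 or 1")
    p = table[:, item]
    lik = p if response == 1 else 1.0 - p
    pi = state.pi * lik
    total = pi.sum()
    if total <= 0:
        raise FloatingPointError("zero posterior normalizing constant")
    return PosteriorState(
        pi=pi / total,
        administered=state.administered + [item],
        responses=state.responses + [response],
    )


# ---------------------------------------------------------------------------
# KL machinery and MPWKL
# ---------------------------------------------------------------------------

def kl_matrices(table: np.ndarray) -> np.ndarray:
    """Pairwise item KL matrices A, shape (J, C, C).

    A[j, d, c] = KL( Bernoulli(p_dj) || Bernoulli(p_cj) ) with natural log.
    Precomputed once per bank; identical to on-the-fly computation.
    """
    p = np.clip(table.T, _KL_EPS, 1.0 - _KL_EPS)  # (J, C)
    pd = p[:, :, None]
    pc = p[:, None, :]
    return pd * np.log(pd / pc) + (1.0 - pd) * np.log((1.0 - pd) / (1.0 - pc))


def mpwkl_index(item: int, state: PosteriorState, table: np.ndarray, A: np.ndarray | None = None) -> float:
    """MPWKL index of one item under the current posterior: pi^T A_j pi."""
    if A is None:
        A = kl_matrices(table[:, [item]])
        Aj = A[0]
    else:
        Aj = A[item]
    return float(state.pi @ Aj @ state.pi)


def select_item(
    state: PosteriorState,
    table: np.ndarray,
    available: np.ndarray,
    A: np.ndarray | None = None,
) -> int:
    """Item with the largest MPWKL index among ``available``; ties -> lowest index."""
    available = np.asarray(available)
    if available.size == 0:
        raise ValueError("item pool exhausted")
    if A is None:
        A = kl_matrices(table)
    scores = np.einsum("jdc,d,c->j", A[available], state.pi, state.pi)
    return int(available[int(np.argmax(scores))])


# ---------------------------------------------------------------------------
# Single-session loop (reference path)
# ---------------------------------------------------------------------------

def run_session(
    profile: np.ndarray,
    true_bank: ItemBank,
    est_bank: ItemBank,
    rule: TerminationRule,
    rng: np.random.Generator,
    *,
    examinee: int = 0,
) -> SessionRecord:
    """Run one adaptive session; the scalar reference for the batch runner.

    Selection, posterior updates and termination use ``est_bank``; each
    response is a Bernoulli draw from ``true_bank`` (one uniform variate per
    administered item, in administration order).
    """
    if true_bank.q.shape != est_bank.q.shape or (true_bank.q != est_bank.q).any():
        raise ValueError("true and estimated banks must share the Q-matrix")
    if true_bank.model != est_bank.model:
        raise ValueError("true and estimated banks must share the model")
    from .cdm import class_index, latent_classes

    K = est_bank.n_attributes
    true_table = class_prob_table(true_bank)
    est_table = class_prob_table(est_bank)
    A = kl_matrices(est_table)
    true_c = class_index(profile)
    state = init_posterior(K)
    terminated_by = "max_length"
    for _ in range(rule.max_length):
        available = np.setdiff1d(np.arange(est_bank.n_items), state.administered)
        item = select_item(state, est_table, available, A)
        x = int(rng.random() < true_table[true_c, item])
        state = update_posterior(state, item, x, est_table)
        if state.pi.max() >= rule.epsilon:
            terminated_by = "threshold"
            break
    map_class = int(np.argmax(state.pi))  # ties -> lowest class index
    return SessionRecord(
        examinee=examinee,
        administered=list(state.administered),
        responses=list(state.responses),
        posterior=state.pi,
        map_class=map_class,
        map_estimate=latent_classes(K)[map_class].copy(),
        test_length=len(state.administered),
        terminated_by=terminated_by,
    )


# ---------------------------------------------------------------------------
# Vectorized batch runner
# ---------------------------------------------------------------------------

@dataclass
class SessionBatch:
    """Vectorized session outcomes for N examinees run in lockstep.

    ``items`` and ``responses`` are (N, max_length) with -1 padding past each
    examinee's stop; ``administered`` is the (N, J) boolean exposure matrix.
    ``max_posterior_true`` is the maximum posterior recomputed under the TRUE
    bank on the same items/responses (uniform prior), the denominator of the
    relative measurement precision.
    """

    lengths: np.ndarray
    terminated_by: np.ndarray
    items: np.ndarray
    responses: np.ndarray
    administered: np.ndarray
    posterior: np.ndarray
    map_class: np.ndarray
    max_posterior: np.ndarray
    max_posterior_true: np.ndarray


def run_sessions_batch(
    profiles: np.ndarray,
    true_bank: ItemBank,
    est_bank: ItemBank,
    rule: TerminationRule,
    uniforms: np.ndarray,
    *,
    tables: tuple[np.ndarray, np.ndarray] | None = None,
    A: np.ndarray | None = None,
) -> SessionBatch:
    """Run all examinees' sessions in lockstep (contract: per-examinee results
    identical to :func:`run_session` driven by the same uniform variates).

    ``uniforms`` is an (N, max_length) matrix; examinee i's response at step t
    is 1 iff uniforms[i, t] < true success probability of the selected item.
    Sharing the matrix across termination thresholds pairs the sessions: a
    higher threshold simply extends each session along the same path.
    """
    from .cdm import latent_classes

    profiles = np.asarray(profiles)
    N, K = profiles.shape
    if tables is None:
        true_table, est_table = class_prob_table(true_bank), class_prob_table(est_bank)
    else:
        true_table, est_table = tables
    C, J = est_table.shape
    if A is None:
        A = kl_matrices(est_table)
    M = A.reshape(J, C * C)
    if uniforms.shape[0] != N or uniforms.shape[1] < rule.max_length:
        raise ValueError("uniforms must be (N, >= max_length)")

    true_c = profiles @ (1 << np.arange(K))
    pi = np.full((N, C), 1.0 / C)
    # posterior under TRUE parameters, maintained through the identical update
    # path so that identical banks give bit-identical posteriors (RMP = 1 exactly)
    pi_true = np.full((N, C), 1.0 / C)
    administered = np.zeros((N, J), dtype=bool)
    items_rec = np.full((N, rule.max_length), -1, dtype=np.int32)
    resp_rec = np.full((N, rule.max_length), -1, dtype=np.int8)
    lengths = np.zeros(N, dtype=np.int32)
    done = np.zeros(N, dtype=bool)
    terminated_by = np.full(N, "max_length", dtype="<U10")

    for step in range(rule.max_length):
        idx = np.flatnonzero(~done)
        if idx.size == 0:
            break
        Pi = pi[idx]
        W = (Pi[:, :, None] * Pi[:, None, :]).reshape(idx.size, C * C)
        scores = W @ M.T  # (n_active, J)
        scores[administered[idx]] = -np.inf
        items = np.argmax(scores, axis=1).astype(np.int32)  # ties -> lowest index
        x = (uniforms[idx, step] < true_table[true_c[idx], items]).astype(np.int8)
        p_est = est_table[:, items].T  # (n_active, C)
        lik = np.where(x[:, None] == 1, p_est, 1.0 - p_est)
        Pi = Pi * lik
        Pi /= Pi.sum(axis=1, keepdims=True)
        pi[idx] = Pi
        p_true = true_table[:, items].T
        lik_true = np.where(x[:, None] == 1, p_true, 1.0 - p_true)
        Pt = pi_true[idx] * lik_true
        Pt /= Pt.sum(axis=1, keepdims=True)
        pi_true[idx] = Pt
        administered[idx, items] = True
        items_rec[idx, step] = items
        resp_rec[idx, step] = x
        lengths[idx] = step + 1
        crossed = Pi.max(axis=1) >= rule.epsilon
        stopped = idx[crossed]
        done[stopped] = True
        terminated_by[stopped] = "threshold"

    return SessionBatch(
        lengths=lengths,
        terminated_by=terminated_by,
        items=items_rec,
        responses=resp_rec,
        administered=administered,
        posterior=pi,
        map_class=np.argmax(pi, axis=1),
        max_posterior=pi.max(axis=1),
        max_posterior_true=pi_true.max(axis=1),
    )
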