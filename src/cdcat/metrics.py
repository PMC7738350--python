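"""Evaluation statistics for adaptive-session outcomes.

* **PCR** — pattern correct classification rate: fraction of examinees whose
  full estimated attribute profile matches the truth.
* **AACR** — average attribute correct classification rate: fraction of
  correctly classified (examinee, attribute) cells.  PCR <= AACR always.
* **ATL** — average test length under the variable-length rule.
* **RMP** — relative measurement precision: the summed maximum posterior
  under the calibrated parameters divided by the same quantity recomputed
  with the true parameters on the SAME administered items and responses
  (uniform prior both times).  Values above 1 mean the calibrated bank is
  spuriously confident.
* **RTE** — relative test efficiency: summed cognitive diagnostic index
  (CDI) of the administered items under calibrated vs true parameters;
  values above 1 mean the test information is overestimated.

The CDI is an item-level discrimination measure: the inverse-Hamming-weighted
average over ordered latent-class pairs (u, v), u != v, of the item's KL
divergence KL_j(u, v), normalized by the total weight.  Down-weighting pairs
of distant profiles emphasizes an item's power to separate *similar* classes.
A uniform weighting is available for sensitivity analysis.
"""

from __future__ import annotations

import numpy as np

from .cdm import ItemBank, class_prob_table, latent_classes
from .engine import SessionBatch, kl_matrices


# ---------------------------------------------------------------------------
# Classification accuracy
# ---------------------------------------------------------------------------

def pcr(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Fraction of examinees with an exactly correct attribute profile."""
    estimates, truths = np.asarray(estimates), np.asarray(truths)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have equal shapes")
    if estimates.shape[0] == 0:
        raise ValueError("need at least one examinee")
    return float(np.all(estimates == truths, axis=1).mean())


def aacr(estimates: np.ndarray, truths: np.ndarray) -> float:
    """Fraction of correctly classified (examinee, attribute) cells."""
    estimates, truths = np.asarray(estimates), np.asarray(truths)
    if estimates.shape != truths.shape:
        raise ValueError("estimates and truths must have equal shapes")
    if estimates.shape[0] == 0:
        raise ValueError("need at least one examinee")
    return float((estimates == truths).mean())


def atl(lengths: np.ndarray) -> tuple[float, float]:
    """Mean and SD (population) of per-examinee test lengths."""
    lengths = np.asarray(lengths)
    if lengths.size == 0:
        raise ValueError("need at least one session")
    return float(lengths.mean()), float(lengths.std())


# ---------------------------------------------------------------------------
# CDI and efficiency/precision ratios
# ---------------------------------------------------------------------------

def _pair_weights(K: int, weighting: str) -> np.ndarray:
    classes = latent_classes(K)
    ham = (classes[:, None, :] != classes[None, :, :]).sum(axis=2).astype(float)
    off = ham > 0
    w = np.zeros_like(ham)
    if weighting == "inv_hamming":
        w[off] = 1.0 / ham[off]
    elif weighting == "uniform":
        w[off] = 1.0
    else:
        raise ValueError(f"unknown CDI weighting {weighting!r}")
    return w


def cdi_items(
    table: np.ndarray, *, weighting: str = "inv_hamming", A: np.ndarray | None = None
) -> np.ndarray:
    """CDI of every item: weighted average of pairwise class KL divergences.

    ``table`` is the (2^K, J) class probability table; returns a length-J
    vector.  An item whose success probability is identical across classes
    carries no diagnostic information and scores 0.
    """
    C, J = table.shape
    K = int(np.log2(C))
    if 2**K != C:
        raise ValueError("table must have 2^K rows")
    if A is None:
        A = kl_matrices(table)  # (J, C, C)
    w = _pair_weights(K, weighting)
    return np.einsum("jdc,dc->j", A, w) / w.sum()


def cdi_item(item: int, table: np.ndarray, *, weighting: str = "inv_hamming") -> float:
    """CDI of a single item (convenience wrapper over :func:`cdi_items`)."""
    return float(cdi_items(table[:, [item]], weighting=weighting)[0])


def rmp(batch: SessionBatch) -> float:
    """Relative measurement precision of a session batch.

    Ratio of summed maximum posteriors: calibrated-bank posterior (the one
    the engine actually used) over the true-bank posterior rescored on the
    same items and responses.  Identity banks give exactly 1.
    """
    return float(batch.max_posterior.sum() / batch.max_posterior_true.sum())


def rte(
    batch: SessionBatch,
    true_bank: ItemBank,
    est_bank: ItemBank,
    *,
    weighting: str = "inv_hamming",
    cdi_true: np.ndarray | None = None,
    cdi_est: np.ndarray | None = None,
) -> float:
    """Relative test efficiency of a session batch.

    Sums each examinee's administered-item CDIs under calibrated parameters
    and divides by the same sum under true parameters — same items, different
    parameters.  Identity banks give exactly 1.
    """
    if cdi_est is None:
        cdi_est = cdi_items(class_prob_table(est_bank), weighting=weighting)
    if cdi_true is None:
        cdi_true = cdi_items(class_prob_table(true_bank), weighting=weighting)
    num = batch.administered @ cdi_est
    den = batch.administered @ cdi_true
    return float(num.sum() / den.sum())
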