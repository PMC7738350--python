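"""CSV readers/writers for Q-matrices and item banks.

Item-bank CSV layout: one row per item with ``item_id``, ``q_1..q_K``, then
model-specific parameter columns —

* DINA: ``s``, ``g``
* RRUM: ``pi_star``, ``r_star_1..r_star_K`` (blank where q_jk = 0)
* CRUM: ``delta_0``, ``delta_1..delta_K`` (blank where q_jk = 0)

The model is inferred from the header on read; all bank invariants are
re-validated by :class:`~cdcat.cdm.ItemBank`.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cdm import ItemBank, validate_q_matrix


def write_q_matrix(q: np.ndarray, path: str | Path) -> None:
    q = validate_q_matrix(q)
    K = q.shape[1]
    pd.DataFrame(q, columns=[f"q_{k+1}" for k in range(K)]).to_csv(path, index=False)


def read_q_matrix(path: str | Path) -> np.ndarray:
    return validate_q_matrix(pd.read_csv(path).to_numpy())


def write_bank(bank: ItemBank, path: str | Path) -> None:
    J, K = bank.q.shape
    df = pd.DataFrame({"item_id": np.arange(1, J + 1)})
    for k in range(K):
        df[f"q_{k+1}"] = bank.q[:, k]
    p = bank.params
    if bank.model == "DINA":
        df["s"], df["g"] = p["s"], p["g"]
    elif bank.model == "RRUM":
        df["pi_star"] = p["pi_star"]
        for k in range(K):
            df[f"r_star_{k+1}"] = p["r_star"][:, k]
    else:
        df["delta_0"] = p["delta0"]
        for k in range(K):
            df[f"delta_{k+1}"] = p["delta"][:, k]
    df.to_csv(path, index=False, float_format="%.10g")


def read_bank(path: str | Path, quality: str | None = None) -> ItemBank:
    df = pd.read_csv(path)
    K = sum(c.startswith("q_") for c in df.columns)
    q = df[[f"q_{k+1}" for k in range(K)]].to_numpy()
    cols = set(df.columns)
    if {"s", "g"} <= cols:
        model, params = "DINA", {"s": df["s"].to_numpy(), "g": df["g"].to_numpy()}
    elif "pi_star" in cols:
        r = df[[f"r_star_{k+1}" for k in range(K)]].to_numpy()
        model, params = "RRUM", {"pi_star": df["pi_star"].to_numpy(), "r_star": r}
    elif "delta_0" in cols:
        d = df[[f"delta_{k+1}" for k in range(K)]].to_numpy()
        model, params = "CRUM", {"delta0": df["delta_0"].to_numpy(), "delta": d}
    else:
        raise ValueError(f"cannot infer model from columns {sorted(cols)}")
    return ItemBank(model=model, q=q, params=params, quality=quality)
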