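"""Tissue-specific probeset calling by three empirical criteria.

A probeset is called specific to its highest-expressing tissue when, on the
replicate-averaged log2 matrix: (1) the top tissue's value strictly exceeds
the detectability threshold (default 6.5); (2) the z-score of the top value
— computed over all tissues, sample standard deviation — strictly exceeds 2;
and (3) the top value is at least one log2 unit above the runner-up.
Non-comparable extra tissues (e.g. whole-embryo samples present in only some
species) are dropped before anything is computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .expression import DEFAULT_EXPRESSION_THRESHOLD, ExpressionMatrix

__all__ = ["TissueSpecificCall", "tissue_zscores", "call_tissue_specific"]

DEFAULT_Z_CUT = 2.0
DEFAULT_MARGIN_CUT = 1.0


@dataclass(frozen=True)
class TissueSpecificCall:
    probeset: str
    tissue: str
    max_value: float
    zscore: float
    margin: float


def tissue_zscores(profile: np.ndarray, ddof: int = 1, exclude_self: bool = False) -> np.ndarray:
    """Per-tissue z-scores of a log2 profile.

    By default each tissue is scored against the mean and sample standard
    deviation of the whole profile, itself included.  ``exclude_self=True``
    scores each tissue against the remaining T−1 tissues instead.  A
    constant profile has sd 0 and returns all zeros (it can never be
    tissue-specific).
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("profile must be a 1-D vector with T >= 3")
    if not exclude_self:
        sd = x.std(ddof=ddof)
        if sd == 0:
            return np.zeros_like(x)
        return (x - x.mean()) / sd
    out = np.empty_like(x)
    for t in range(x.size):
        rest = np.delete(x, t)
        sd = rest.std(ddof=ddof)
        out[t] = 0.0 if sd == 0 else (x[t] - rest.mean()) / sd
    return out


def call_tissue_specific(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    z_cut: float = DEFAULT_Z_CUT,
    margin_cut: float = DEFAULT_MARGIN_CUT,
    exclude_tissues: Iterable[str] = (),
    ddof: int = 1,
) -> list[TissueSpecificCall]:
    """Apply the three criteria to every probeset of an averaged matrix.

    Emits at most one call per probeset (its single winning tissue).  A tie
    for the maximum gives margin 0 and is never called.  Criteria 1 and 2
    are strict inequalities; criterion 3 is ``margin >= margin_cut``
    ("at least one log higher").  Calls do not depend on tissue column
    order.
    """
    if not matrix.is_averaged:
        raise ValueError("call_tissue_specific requires a replicate-averaged matrix")
    excl = set(exclude_tissues)
    keep = [t for t in matrix.data.columns if t not in excl]
    if len(keep) < 3:
        raise ValueError("fewer than 3 tissues remain after exclusion")
    data = matrix.data[keep]
    X = data.to_numpy(float)
    n = X.shape[1]

    order = np.argsort(X, axis=1, kind="stable")
    top_idx = order[:, -1]
    rows = np.arange(X.shape[0])
    top = X[rows, top_idx]
    second = X[rows, order[:, -2]]
    margin = top - second

    mean = X.mean(axis=1)
    sd = X.std(axis=1, ddof=ddof)
    with np.errstate(invalid="ignore", divide="ignore"):
        z_top = np.where(sd > 0, (top - mean) / sd, 0.0)

    # a tie for the maximum gives margin 0 and can never satisfy margin_cut>0,
    # but guard margin_cut<=0 configurations too
    tie = top == second
    called = (top > threshold) & (z_top > z_cut) & (margin >= margin_cut) & ~tie

    calls = [
        TissueSpecificCall(
            probeset=str(data.index[i]),
            tissue=keep[top_idx[i]],
            max_value=float(top[i]),
            zscore=float(z_top[i]),
            margin=float(margin[i]),
        )
        for i in np.flatnonzero(called)
    ]
    return sorted(calls, key=lambda c: c.probeset)


def calls_to_frame(calls: list[TissueSpecificCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probeset": [c.probeset for c in calls],
            "tissue": [c.tissue for c in calls],
            "max_value": [c.max_value for c in calls],
            "zscore": [c.zscore for c in calls],
            "margin": [c.margin for c in calls],
        }
    )
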