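"""Coupling between sense and antisense expression at shared loci.

Sense and antisense arrays are normalized separately, so absolute levels are
not comparable between protocols; this module therefore reports only
correlations.  Two views are provided: the per-tissue Pearson correlation of
sense vs antisense intensity across probesets, and the correlation between
the cross-species expression divergence of a locus measured on the sense
protocol and on the antisense protocol (paired through the shared probeset
identifier, since both protocols interrogate the same exonic locus).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

__all__ = ["CorrelationRecord", "per_tissue_correlation", "divergence_correlation"]


@dataclass(frozen=True)
class CorrelationRecord:
    scope: str  # tissue label, or "divergence"
    r: float
    n: int
    defined: bool = True


def per_tissue_correlation(
    sense_matrix: ExpressionMatrix, antisense_matrix: ExpressionMatrix
) -> list[CorrelationRecord]:
    """Pearson r between sense and antisense intensity, per tissue.

    Matrices must be replicate-averaged, from the same species, and share
    their probeset universe; rows are matched on probeset id.  A tissue
    where either protocol is constant across probesets yields an undefined
    (flagged) record.
    """
    if sense_matrix.species != antisense_matrix.species:
        raise ValueError("matrices must come from the same species")
    shared_t = [t for t in sense_matrix.tissues if t in set(antisense_matrix.tissues)]
    common = sense_matrix.data.index.intersection(antisense_matrix.data.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared probesets")
    records = []
    for tissue in shared_t:
        s = sense_matrix.data.loc[common, tissue].to_numpy(float)
        a = antisense_matrix.data.loc[common, tissue].to_numpy(float)
        if np.ptp(s) == 0 or np.ptp(a) == 0:
            records.append(CorrelationRecord(tissue, float("nan"), len(common), defined=False))
            continue
        r = float(stats.pearsonr(s, a).statistic)
        records.append(CorrelationRecord(tissue, r, len(common)))
    return records


def divergence_correlation(
    sense_records: pd.DataFrame,
    antisense_records: pd.DataFrame,
    key: str = "probeset_a",
) -> CorrelationRecord:
    """Correlation of sense vs antisense expression divergence across loci.

    Both inputs are divergence record tables restricted to their
    orthologous set; they are inner-joined on ``key`` (the shared locus
    identifier).  Returns the Pearson r over the joined loci.
    """
    s = sense_records.loc[
        sense_records.get("set_label", "orthologous") == "orthologous", [key, "divergence"]
    ]
    a = antisense_records.loc[
        antisense_records.get("set_label", "orthologous") == "orthologous", [key, "divergence"]
    ]
    if s[key].duplicated().any() or a[key].duplicated().any():
        raise ValueError("duplicate locus keys in divergence records")
    joined = s.merge(a, on=key, suffixes=("_sense", "_antisense"))
    if len(joined) == 0:
        raise ValueError(f"empty join on key {key!r}: no shared loci between the two tables")
    if len(joined) < 3:
        raise ValueError("need at least 3 joined loci")
    r = float(
        stats.pearsonr(
            joined["divergence_sense"], joined["divergence_antisense"]
        ).statistic
    )
    return CorrelationRecord("divergence", r, len(joined))


def records_to_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "scope": [c.scope for c in records],
            "r": [c.r for c in records],
            "n": [c.n for c in records],
            "defined": [c.defined for c in records],
        }
    )
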