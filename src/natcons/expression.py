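"""Expression matrices and their elementary transforms.

The unit of measurement is the probeset: a set of microarray probes
interrogating one exonic locus on one strand.  All intensities are RMA-style
log2 values and are never re-logged.  The elementary transforms here are the
building blocks of the divergence analysis: replicate averaging, conversion
of a per-tissue profile to relative abundance, and the detectability filter
applied to cross-species probeset pairs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "average_replicates",
    "relative_abundance",
    "pair_expressed_filter",
    "DEFAULT_EXPRESSION_THRESHOLD",
]

#: log2 intensity above which a probeset counts as detected (the proxy for a
#: detection-above-background p-value < 0.01 on these arrays).
DEFAULT_EXPRESSION_THRESHOLD = 6.5

_REP_RE = re.compile(r"^(?P<tissue>.+)_rep(?P<rep>\d+)$")


@dataclass
class ExpressionMatrix:
    """A per-species, per-strand-protocol table of log2 intensities.

    Parameters
    ----------
    species :
        Species label (e.g. ``"mouse"``).
    protocol :
        ``"sense"`` or ``"antisense"`` — which strand the labeling protocol
        makes the array report.
    data :
        DataFrame indexed by probeset id.  Columns are either
        ``<tissue>_rep<k>`` (raw, replicated) or bare ``<tissue>`` names
        (after :func:`average_replicates`).
    """

    species: str
    protocol: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.protocol not in ("sense", "antisense"):
            raise ValueError(f"protocol must be 'sense' or 'antisense', got {self.protocol!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate probeset ids: {dups[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def is_averaged(self) -> bool:
        """True when no column carries a ``_rep<k>`` suffix."""
        return not any(_REP_RE.match(c) for c in self.data.columns)

    @property
    def tissues(self) -> list[str]:
        """Ordered unique tissue labels (replicate suffixes stripped)."""
        seen: dict[str, None] = {}
        for c in self.data.columns:
            m = _REP_RE.match(c)
            seen.setdefault(m.group("tissue") if m else c, None)
        return list(seen)

    def profile(self, probeset: str) -> np.ndarray:
        """Per-column intensity vector for one probeset."""
        return self.data.loc[probeset].to_numpy(dtype=float)


def _replicate_groups(columns: list[str]) -> dict[str, list[str]]:
    groups: dict[str, list[str]] = {}
    for c in columns:
        m = _REP_RE.match(c)
        tissue = m.group("tissue") if m else c
        groups.setdefault(tissue, []).append(c)
    return groups


def average_replicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Collapse ``<tissue>_rep<k>`` columns to one column per tissue.

    Each averaged value is the arithmetic mean of that tissue's replicate
    log2 values (averaging is done on the log scale, matching the upstream
    normalization convention).  Probeset order is preserved.
    """
    groups = _replicate_groups(list(matrix.data.columns))
    out = pd.DataFrame(
        {tissue: matrix.data[cols].mean(axis=1) for tissue, cols in groups.items()},
        index=matrix.data.index,
    )
    return ExpressionMatrix(species=matrix.species, protocol=matrix.protocol, data=out)


def relative_abundance(profile: np.ndarray) -> np.ndarray:
    """Per-tissue fraction of a probeset's summed log2 intensity.

    ``a[t] = e[t] / sum_t e[t]``.  Defined only for strictly positive log
    intensities (the regime of RMA-normalized arrays); the output sums to 1.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector with at least 2 tissues")
    if np.any(x <= 0):
        raise ValueError("relative abundance requires strictly positive log intensities")
    return x / x.sum()


def relative_abundance_matrix(profiles: np.ndarray) -> np.ndarray:
    """Row-wise :func:`relative_abundance` for an ``(n, T)`` array."""
    x = np.asarray(profiles, dtype=float)
    if np.any(x <= 0):
        raise ValueError("relative abundance requires strictly positive log intensities")
    return x / x.sum(axis=-1, keepdims=True)


def pair_expressed_filter(
    profile_a: np.ndarray,
    profile_b: np.ndarray,
    threshold: float = DEFAULT_EXPRESSION_THRESHOLD,
    mode: str = "pair",
) -> bool:
    """Detectability filter for a cross-species probeset pair.

    In ``mode="pair"`` (default) the pair passes when *any* of the 2·T
    averaged intensities strictly exceeds ``threshold`` — either member
    suffices.  ``mode="each"`` requires every member to have at least one
    tissue above the threshold.  The inequality is strict.
    """
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"profile length mismatch: {a.shape} vs {b.shape}")
    if mode == "pair":
        return bool(max(a.max(), b.max()) > threshold)
    if mode == "each":
        return bool(a.max() > threshold and b.max() > threshold)
    raise ValueError(f"unknown filter mode {mode!r}")
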