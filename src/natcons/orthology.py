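"""Exon- and gene-level orthology mapping.

Exon orthology is called from sequence alone: two exons are orthologous when
their global (end-to-end) alignment identity exceeds a cutoff, by convention
80%.  Identity is computed from a Needleman–Wunsch alignment with linear gap
penalties; the denominator counts *all* alignment columns, gaps included —
the strictest reading of "global identity".  When one exon clears the cutoff
against several exons of the other species only the highest-identity hit is
kept.  Gene-level orthology is taken from a homology-group table (one group
id, one gene per species per row, HomoloGene-style) joined to per-species
gene→probeset annotations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

from intervaltree import IntervalTree

__all__ = [
    "AlignmentScoring",
    "OrthologPair",
    "global_identity",
    "map_orthologs",
    "remove_dual_strand_overlaps",
    "gene_orthologs",
]

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman–Wunsch scoring: match/mismatch per column, linear gap."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0

    def __post_init__(self) -> None:
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap penalty must be negative")


DEFAULT_SCORING = AlignmentScoring()

#: minimum global identity for an exon pair to be considered orthologous
DEFAULT_MIN_IDENTITY = 0.80


@dataclass(frozen=True)
class OrthologPair:
    """A cross-species probeset pair with its provenance.

    ``identity`` is the global alignment identity for exon-level pairs and
    ``None`` for gene-level pairs (which come from the homology table, not
    from sequence).
    """

    probeset_a: str
    probeset_b: str
    species_a: str
    species_b: str
    level: str  # "exon" | "gene"
    identity: float | None = None

    def __post_init__(self) -> None:
        if self.level not in ("exon", "gene"):
            raise ValueError(f"level must be 'exon' or 'gene', got {self.level!r}")
        if (self.identity is None) != (self.level == "gene"):
            raise ValueError("identity must be present iff level='exon'")


def _check_sequence(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"{name}: non-ACGT characters {sorted(bad)}")
    return seq


# traceback pointer codes
_DIAG, _UP, _LEFT = 0, 1, 2


def _nw_align(a: str, b: str, scoring: AlignmentScoring) -> tuple[float, int, int]:
    """Global alignment of ``a`` vs ``b``.

    Returns ``(score, identical_columns, total_columns)``.  Ties between
    cell predecessors are broken diagonal > up > left, which makes the
    traceback (and hence the identity) deterministic.
    """
    n, m = len(a), len(b)
    av = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    bv = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    match, mismatch, gap = scoring.match, scoring.mismatch, scoring.gap

    ptr = np.empty((n + 1, m + 1), dtype=np.uint8)
    ptr[0, :] = _LEFT
    ptr[:, 0] = _UP
    j_idx = np.arange(1, m + 1)
    prev = gap * np.arange(m + 1, dtype=float)
    for i in range(1, n + 1):
        diag = prev[:-1] + np.where(bv == av[i - 1], match, mismatch)
        up = prev[1:] + gap
        no_left = np.maximum(diag, up)
        # left moves have linear cost, so the running best over j is a prefix max
        f = np.maximum.accumulate(np.concatenate(([prev[0] + gap], no_left - gap * j_idx)))
        cur = np.empty(m + 1)
        cur[0] = prev[0] + gap
        cur[1:] = np.maximum(no_left, f[:-1] + gap * j_idx)
        row_ptr = np.where(cur[1:] == diag, _DIAG, np.where(cur[1:] == up, _UP, _LEFT))
        ptr[i, 1:] = row_ptr
        prev = cur

    score = float(prev[-1])
    # traceback: count identical columns and total columns
    i, j = n, m
    ident = 0
    cols = 0
    while i > 0 or j > 0:
        p = ptr[i, j]
        cols += 1
        if p == _DIAG:
            if av[i - 1] == bv[j - 1]:
                ident += 1
            i -= 1
            j -= 1
        elif p == _UP:
            i -= 1
        else:
            j -= 1
    return score, ident, cols


def global_identity(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Fraction of identical columns in the optimal global alignment.

    Gap columns count in the denominator.  The result is symmetric in its
    arguments (the two sequences are put in a canonical order before
    aligning, so tie-breaking cannot depend on argument order) and lies in
    [0, 1], reaching 1 only for identical sequences.
    """
    a = _check_sequence(seq_a, "seq_a")
    b = _check_sequence(seq_b, "seq_b")
    if a > b:
        a, b = b, a
    _, ident, cols = _nw_align(a, b, scoring)
    return ident / cols


def _edlib_prescreen_ok(a: str, b: str, min_identity: float) -> bool:
    """Lossless candidate prescreen via banded edit distance.

    If the optimal global alignment of ``a`` and ``b`` has identity
    ``>= min_identity`` then its non-identical columns number at most
    ``(1 - min_identity) * columns <= (1 - min_identity) * (|a| + |b|)``,
    and the unit-cost edit distance cannot exceed the non-identical column
    count of any alignment.  Pairs beyond that bound can never be retained,
    so skipping them changes nothing.
    """
    k = int(np.ceil((1.0 - min_identity) * (len(a) + len(b))))
    res = edlib.align(a, b, mode="NW", task="distance", k=k)
    return res["editDistance"] != -1


def map_orthologs(
    seqs_a: dict[str, str],
    seqs_b: dict[str, str],
    species_a: str = "A",
    species_b: str = "B",
    min_identity: float = DEFAULT_MIN_IDENTITY,
    scoring: AlignmentScoring = DEFAULT_SCORING,
    reciprocal: bool = False,
    prescreen: bool = True,
) -> list[OrthologPair]:
    """Call orthologous exon pairs between two species from sequence.

    For each exon of species A, every B exon with global identity strictly
    above ``min_identity`` is a candidate; only the highest-identity
    candidate is kept, ties going to the lexicographically smallest B
    identifier.  With ``reciprocal=True`` a pair is additionally required to
    be the best hit in both directions.  Output is sorted by
    ``(probeset_a, probeset_b)``.
    """
    def as_dict(seqs, name: str) -> dict[str, str]:
        if isinstance(seqs, dict):
            return seqs
        out: dict[str, str] = {}
        for sid, seq in seqs:
            if sid in out:
                raise ValueError(f"duplicate identifier {sid!r} in set {name}")
            out[sid] = seq
        return out

    seqs_a = as_dict(seqs_a, "A")
    seqs_b = as_dict(seqs_b, "B")
    use_prescreen = prescreen and _HAVE_EDLIB
    clean_a = {k: _check_sequence(v, k) for k, v in seqs_a.items()}
    clean_b = {k: _check_sequence(v, k) for k, v in seqs_b.items()}

    def best_hits(queries: dict[str, str], targets: dict[str, str]) -> dict[str, tuple[str, float]]:
        hits: dict[str, tuple[str, float]] = {}
        for qid in sorted(queries):
            qseq = queries[qid]
            best: tuple[float, str] | None = None
            for tid in sorted(targets):
                tseq = targets[tid]
                if use_prescreen and not _edlib_prescreen_ok(qseq, tseq, min_identity):
                    continue
                ident = global_identity(qseq, tseq, scoring)
                if ident > min_identity and (best is None or ident > best[0]):
                    best = (ident, tid)
            if best is not None:
                hits[qid] = (best[1], best[0])
        return hits

    forward = best_hits(clean_a, clean_b)
    if reciprocal:
        backward = best_hits(clean_b, clean_a)
        forward = {
            qa: (qb, ident)
            for qa, (qb, ident) in forward.items()
            if backward.get(qb, (None,))[0] == qa
        }
    pairs = [
        OrthologPair(qa, qb, species_a, species_b, level="exon", identity=ident)
        for qa, (qb, ident) in forward.items()
    ]
    return sorted(pairs, key=lambda p: (p.probeset_a, p.probeset_b))


def remove_dual_strand_overlaps(
    probesets: pd.DataFrame, transcripts: pd.DataFrame
) -> set[str]:
    """Drop probesets overlapped by annotated transcripts on *both* strands.

    ``probesets`` needs columns ``name, chrom, start, end``; ``transcripts``
    needs ``chrom, start, end, strand``.  Coordinates are 0-based half-open
    (BED convention): a book-ended interval (``end == start``) does not
    overlap.  Returns the retained probeset names.
    """
    if (~transcripts["strand"].isin(["+", "-"])).any():
        raise ValueError("transcript annotation contains strandless records")

    trees: dict[tuple[str, str], IntervalTree] = {}
    for row in transcripts.itertuples(index=False):
        if row.end <= row.start:
            continue
        trees.setdefault((row.chrom, row.strand), IntervalTree()).addi(row.start, row.end)

    retained: set[str] = set()
    for row in probesets.itertuples(index=False):
        plus = trees.get((row.chrom, "+"))
        minus = trees.get((row.chrom, "-"))
        hit_plus = bool(plus is not None and plus.overlap(row.start, row.end))
        hit_minus = bool(minus is not None and minus.overlap(row.start, row.end))
        if not (hit_plus and hit_minus):
            retained.add(row.name)
    return retained


def gene_orthologs(
    homology: pd.DataFrame,
    annotation_a: dict[str, list[str]],
    annotation_b: dict[str, list[str]],
    species_a: str,
    species_b: str,
) -> list[OrthologPair]:
    """Gene-level ortholog pairs from a homology-group table.

    ``homology`` has columns ``group_id, species, gene_id``; the annotations
    map gene id → probeset ids for each species.  For every group containing
    both species, all cross products of mappable probesets are emitted.
    Genes absent from the annotation are skipped with a warning; groups
    missing either species are skipped silently.
    """
    pairs: list[OrthologPair] = []
    for _, group in homology.groupby("group_id", sort=True):
        genes_a = group.loc[group["species"] == species_a, "gene_id"].tolist()
        genes_b = group.loc[group["species"] == species_b, "gene_id"].tolist()
        if not genes_a or not genes_b:
            continue
        ps_a: list[str] = []
        ps_b: list[str] = []
        for g in genes_a:
            if g not in annotation_a:
                logger.warning("gene %s (%s) missing from annotation; skipped", g, species_a)
                continue
            ps_a.extend(annotation_a[g])
        for g in genes_b:
            if g not in annotation_b:
                logger.warning("gene %s (%s) missing from annotation; skipped", g, species_b)
                continue
            ps_b.extend(annotation_b[g])
        for pa, pb in product(sorted(ps_a), sorted(ps_b)):
            pairs.append(OrthologPair(pa, pb, species_a, species_b, level="gene"))
    return sorted(pairs, key=lambda p: (p.probeset_a, p.probeset_b))


def pairs_to_frame(pairs: list[OrthologPair]) -> pd.DataFrame:
    """Tabulate ortholog pairs (TSV-ready)."""
    return pd.DataFrame(
        {
            "probeset_a": [p.probeset_a for p in pairs],
            "probeset_b": [p.probeset_b for p in pairs],
            "species_a": [p.species_a for p in pairs],
            "species_b": [p.species_b for p in pairs],
            "level": [p.level for p in pairs],
            "identity": [p.identity if p.identity is not None else np.nan for p in pairs],
        }
    )
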