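"""Novelty screening of probeset target sequences.

A probeset is *novel* when its target sequence has no perfect match in
either reference database (a RefSeq-like and an EST-like FASTA).  "Perfect
match" means the query occurs as an exact, full-length, contiguous substring
of a reference record — and only in the *reverse-complement* orientation:
the arrays report the strand opposite to the annotated exon, so a known
antisense transcript shows up as the reverse complement of the probeset
target in the transcript databases.  A forward-orientation-only match does
not count.

Matching is done with a k-mer seed index over the references followed by
exact extension, which is equivalent to a full substring scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio.Seq import reverse_complement

__all__ = ["ReferenceIndex", "build_reference_index", "screen_probesets"]

logger = logging.getLogger(__name__)

DEFAULT_WORD_SIZE = 11


@dataclass
class ReferenceIndex:
    """Exact-substring index over one reference database.

    ``seeds`` maps every k-mer of every reference sequence to its
    occurrence positions; a query is confirmed by extending its first k-mer
    seed to a full-length comparison.  k-mers containing N are not indexed
    (N never matches).
    """

    source: str
    k: int
    sequences: dict[str, str]
    seeds: dict[str, list[tuple[str, int]]] = field(repr=False, default_factory=dict)

    def contains(self, query: str) -> bool:
        """True iff ``query`` is an exact contiguous substring of any record."""
        q = query.upper()
        if len(q) < self.k:
            # shorter than the seed size: fall back to a direct scan
            logger.info("query shorter than k=%d; direct scan", self.k)
            return any(q in s for s in self.sequences.values())
        seed = q[: self.k]
        for ref_id, pos in self.seeds.get(seed, ()):
            if self.sequences[ref_id][pos : pos + len(q)] == q:
                return True
        return False


def build_reference_index(
    sequences: dict[str, str], k: int = DEFAULT_WORD_SIZE, source: str = "reference"
) -> ReferenceIndex:
    """Index a reference database (id → sequence) for exact-substring queries."""
    if k < 8:
        raise ValueError("word size k must be >= 8")
    if not sequences:
        raise ValueError("empty reference database")
    clean = {rid: seq.upper() for rid, seq in sequences.items()}
    for rid, seq in clean.items():
        if set(seq) - set("ACGTN"):
            raise ValueError(f"reference {rid}: characters outside ACGTN")
    seeds: dict[str, list[tuple[str, int]]] = {}
    for rid in sorted(clean):
        seq = clean[rid]
        for pos in range(len(seq) - k + 1):
            word = seq[pos : pos + k]
            if "N" in word:
                continue
            seeds.setdefault(word, []).append((rid, pos))
    return ReferenceIndex(source=source, k=k, sequences=clean, seeds=seeds)


def screen_probesets(
    queries: dict[str, str],
    refseq_index: ReferenceIndex,
    est_index: ReferenceIndex,
    both_strands: bool = False,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify each query as known or novel against two reference databases.

    A query is KNOWN iff its reverse complement is an exact full-length
    substring of some record in either database (``both_strands=True`` also
    accepts forward-orientation matches, for diagnostics).  Queries
    containing N are flagged and skipped.  Returns a per-probeset table
    (``probeset, status, db_hit``) and summary counts in the three classic
    rows: absent from RefSeq, absent from EST, absent from both (= novel).
    """
    if not queries:
        raise ValueError("no query sequences supplied")
    rows = []
    for qid in sorted(queries):
        seq = queries[qid].upper()
        if "N" in seq:
            logger.warning("query %s contains N; skipped", qid)
            rows.append((qid, "skipped", "none"))
            continue
        probes = [reverse_complement(seq)]
        if both_strands:
            probes.append(seq)
        in_refseq = any(refseq_index.contains(p) for p in probes)
        in_est = any(est_index.contains(p) for p in probes)
        if in_refseq and in_est:
            hit = "both"
        elif in_refseq:
            hit = "refseq"
        elif in_est:
            hit = "est"
        else:
            hit = "none"
        status = "known" if (in_refseq or in_est) else "novel"
        rows.append((qid, status, hit))
    table = pd.DataFrame(rows, columns=["probeset", "status", "db_hit"])
    screened = table[table["status"] != "skipped"]
    summary = {
        "n_queries": int(len(screened)),
        "not_in_refseq": int((~screened["db_hit"].isin(["refseq", "both"])).sum()),
        "not_in_est": int((~screened["db_hit"].isin(["est", "both"])).sum()),
        "not_in_either": int((screened["status"] == "novel").sum()),
    }
    return table, summary
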