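import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from natcons.orthology import (
    AlignmentScoring,
    OrthologPair,
    gene_orthologs,
    global_identity,
    map_orthologs,
    remove_dual_strand_overlaps,
)
from natcons.simulate import mutate_sequence, random_sequence

from oracles import oracle_global_identity

dna = st.text(alphabet="ACGT", min_size=1, max_size=40)


class TestGlobalIdentity:
    def test_identical_sequences(self):
        assert global_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_forced_ungapped_alignment(self):
        assert global_identity("ACGT", "ACGA") == 0.75

    def test_matches_bruteforce_dp_on_random_pairs(self):
        rng = np.random.default_rng(5150)
        for _ in range(50):
            a = random_sequence(int(rng.integers(5, 61)), rng)
            b = mutate_sequence(a, float(rng.uniform(0, 0.6)), rng)
            # occasionally make lengths differ so gaps are exercised
            if rng.random() < 0.5:
                b = b[: int(rng.integers(1, len(b) + 1))]
            assert global_identity(a, b) == pytest.approx(
                oracle_global_identity(a, b), abs=1e-12
            )

    @given(dna, dna)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_and_bounded(self, a, b):
        ident = global_identity(a, b)
        assert 0.0 <= ident <= 1.0
        assert ident == global_identity(b, a)
        assert global_identity(a, a) == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_identity("", "ACGT")

    def test_scoring_validation(self):
        with pytest.raises(ValueError):
            AlignmentScoring(match=1, mismatch=2, gap=-1)
        with pytest.raises(ValueError):
            AlignmentScoring(gap=0)


class TestMapOrthologs:
    def test_disjoint_sequences_yield_nothing(self, rng):
        a = {"a1": random_sequence(80, rng)}
        b = {"b1": random_sequence(80, rng), "b2": random_sequence(80, rng)}
        assert map_orthologs(a, b) == []

    def test_best_hit_wins(self, rng):
        base = random_sequence(100, rng)
        a = {"a1": base}
        b = {
            "b_far": mutate_sequence(base, 0.15, rng),   # ~0.85 identity
            "b_near": mutate_sequence(base, 0.04, rng),  # ~0.96 identity
        }
        pairs = map_orthologs(a, b)
        assert len(pairs) == 1
        assert pairs[0].probeset_b == "b_near"
        assert pairs[0].identity > 0.9

    def test_tie_breaks_to_smallest_identifier(self, rng):
        base = random_sequence(60, rng)
        pairs = map_orthologs({"a1": base}, {"b2": base, "b1": base})
        assert [(p.probeset_a, p.probeset_b) for p in pairs] == [("a1", "b1")]

    def test_each_query_appears_at_most_once(self, small_dataset):
        pairs = map_orthologs(
            small_dataset.exon_sequences["human"], small_dataset.exon_sequences["mouse"]
        )
        ids_a = [p.probeset_a for p in pairs]
        assert len(ids_a) == len(set(ids_a))

    def test_reciprocal_mode_injective_on_b(self, rng):
        base = random_sequence(90, rng)
        a = {"a1": base, "a2": mutate_sequence(base, 0.02, rng)}
        b = {"b1": mutate_sequence(base, 0.02, rng)}
        recip = map_orthologs(a, b, reciprocal=True)
        ids_b = [p.probeset_b for p in recip]
        assert len(ids_b) == len(set(ids_b))

    def test_recovers_generator_truth_exactly(self, small_dataset):
        ds = small_dataset
        g = ds.config.n_ortholog_groups
        pairs = map_orthologs(
            ds.exon_sequences["mouse"], ds.exon_sequences["rat"],
            species_a="mouse", species_b="rat",
        )
        found = {(p.probeset_a, p.probeset_b) for p in pairs}
        expected = {(f"mouse_ps{i:05d}", f"rat_ps{i:05d}") for i in range(g)}
        assert found == expected

    def test_prescreen_changes_nothing(self, rng):
        base = random_sequence(70, rng)
        a = {"a1": base, "a2": random_sequence(70, rng)}
        b = {"b1": mutate_sequence(base, 0.08, rng), "b2": random_sequence(70, rng)}
        with_ps = map_orthologs(a, b, prescreen=True)
        without = map_orthologs(a, b, prescreen=False)
        assert [(p.probeset_a, p.probeset_b, p.identity) for p in with_ps] == [
            (p.probeset_a, p.probeset_b, p.identity) for p in without
        ]

    def test_duplicate_identifiers_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            map_orthologs({"x": "ACGT"}, [("y", "ACGT"), ("y", "ACGA")])


def _bed(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


class TestDualStrandRemoval:
    probesets = pd.DataFrame(
        {
            "name": ["p1", "p2", "p3"],
            "chrom": ["chr1", "chr1", "chr1"],
            "start": [100, 500, 900],
            "end": [200, 600, 1000],
            "strand": ["+", "+", "+"],
        }
    )

    def test_single_strand_overlap_retained(self):
        tx = _bed([("chr1", 90, 210, "t1", 0, "+"), ("chr1", 95, 205, "t2", 0, "+")])
        assert remove_dual_strand_overlaps(self.probesets, tx) == {"p1", "p2", "p3"}

    def test_both_strand_overlap_removed(self):
        tx = _bed([("chr1", 90, 210, "t1", 0, "+"), ("chr1", 150, 160, "t2", 0, "-")])
        assert remove_dual_strand_overlaps(self.probesets, tx) == {"p2", "p3"}

    def test_bookended_interval_is_not_overlap(self):
        # '-' transcript ends exactly where p1 starts: half-open, no shared base
        tx = _bed([("chr1", 90, 210, "t1", 0, "+"), ("chr1", 50, 100, "t2", 0, "-")])
        assert "p1" in remove_dual_strand_overlaps(self.probesets, tx)

    def test_strandless_records_rejected(self):
        tx = _bed([("chr1", 90, 210, "t1", 0, ".")])
        with pytest.raises(ValueError, match="strandless"):
            remove_dual_strand_overlaps(self.probesets, tx)

    def test_agrees_with_bruteforce_scan(self, rng):
        n_ps, n_tx = 60, 120
        ps = pd.DataFrame(
            {
                "name": [f"p{i}" for i in range(n_ps)],
                "chrom": rng.choice(["chr1", "chr2"], n_ps),
                "start": rng.integers(0, 5000, n_ps),
                "strand": "+",
            }
        )
        ps["end"] = ps["start"] + rng.integers(1, 300, n_ps)
        tx = pd.DataFrame(
            {
                "chrom": rng.choice(["chr1", "chr2"], n_tx),
                "start": rng.integers(0, 5000, n_tx),
                "name": [f"t{i}" for i in range(n_tx)],
                "score": 0,
                "strand": rng.choice(["+", "-"], n_tx),
            }
        )
        tx["end"] = tx["start"] + rng.integers(1, 300, n_tx)

        def overlaps(a_start, a_end, b_start, b_end):
            return max(a_start, b_start) < min(a_end, b_end)

        expected = set()
        for p in ps.itertuples(index=False):
            hits = {"+": False, "-": False}
            for t in tx.itertuples(index=False):
                if t.chrom == p.chrom and overlaps(p.start, p.end, t.start, t.end):
                    hits[t.strand] = True
            if not (hits["+"] and hits["-"]):
                expected.add(p.name)
        assert remove_dual_strand_overlaps(ps, tx) == expected


class TestGeneOrthologs:
    homology = pd.DataFrame(
        {
            "group_id": ["G1", "G1", "G1", "G2"],
            "species": ["human", "mouse", "rat", "human"],
            "gene_id": ["hg1", "mg1", "rg1", "hg2"],
        }
    )

    def test_complete_group_emits_pairs(self):
        pairs = gene_orthologs(
            self.homology, {"hg1": ["h_ps1"]}, {"mg1": ["m_ps1", "m_ps2"]}, "human", "mouse"
        )
        assert [(p.probeset_a, p.probeset_b) for p in pairs] == [
            ("h_ps1", "m_ps1"),
            ("h_ps1", "m_ps2"),
        ]
        assert all(p.level == "gene" and p.identity is None for p in pairs)

    def test_single_species_group_skipped(self):
        assert (
            gene_orthologs(self.homology, {"hg2": ["x"]}, {}, "human", "mouse") == []
        )

    def test_unannotated_gene_logged_and_skipped(self, caplog):
        with caplog.at_level(logging.WARNING):
            pairs = gene_orthologs(
                self.homology, {"hg1": ["h_ps1"]}, {}, "human", "mouse"
            )
        assert pairs == []
        assert any("mg1" in r.message for r in caplog.records)

    def test_synthetic_homology_full_recovery(self, small_dataset):
        ds = small_dataset
        pairs = gene_orthologs(
            ds.homology, ds.gene_annotation["human"], ds.gene_annotation["rat"],
            "human", "rat",
        )
        assert len(pairs) == ds.config.n_ortholog_groups


def test_ortholog_pair_invariants():
    with pytest.raises(ValueError, match="identity"):
        OrthologPair("a", "b", "human", "mouse", level="exon", identity=None)
    with pytest.raises(ValueError, match="identity"):
        OrthologPair("a", "b", "human", "mouse", level="gene", identity=0.9)
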