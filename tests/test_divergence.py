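import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from natcons.divergence import (
    alternative_randomization,
    expression_divergence,
    generate_permuted_pairs,
    run_divergence_comparison,
    tissue_correlation_matrix,
    welch_t_test,
)
from natcons.expression import relative_abundance
from natcons.orthology import OrthologPair
from natcons.simulate import simulate_profile_pairs

from conftest import make_matrix
from oracles import oracle_welch

TISSUES9 = [f"t{i}" for i in range(9)]


def make_pairs(n, prefix_a="a", prefix_b="b"):
    return [
        OrthologPair(f"{prefix_a}{i:05d}", f"{prefix_b}{i:05d}", "A", "B",
                     level="exon", identity=0.95)
        for i in range(n)
    ]


def paired_matrices(A, B, tissues=None):
    tissues = tissues or TISSUES9[: A.shape[1]]
    ma = make_matrix(A, tissues, species="A", prefix="a")
    mb = make_matrix(B, tissues, species="B", prefix="b")
    return ma, mb, make_pairs(A.shape[0])


class TestExpressionDivergence:
    def test_identical_profiles_zero(self):
        x = np.array([7.0, 8.0, 9.0])
        assert expression_divergence(x, x) == 0.0

    def test_hand_oracle_reversed_profile(self):
        # abundances (7,8,9)/24 vs (9,8,7)/24 differ by 2/24 in two tissues
        d = expression_divergence(np.array([7.0, 8.0, 9.0]), np.array([9.0, 8.0, 7.0]))
        assert d == pytest.approx(np.sqrt(2) / 12, rel=1e-12)

    def test_disjoint_abundance_approaches_sqrt2(self):
        a = np.array([1000.0, 1e-6])
        b = np.array([1e-6, 1000.0])
        assert expression_divergence(a, b) == pytest.approx(np.sqrt(2), abs=1e-6)

    def test_pearson_measure(self):
        a = np.array([7.0, 8.0, 9.0, 6.0])
        b = np.array([9.0, 8.0, 7.0, 10.0])
        expected = 1.0 - np.corrcoef(a, b)[0, 1]
        assert expression_divergence(a, b, measure="pearson") == pytest.approx(expected)
        with pytest.raises(ValueError, match="constant"):
            expression_divergence(np.full(4, 8.0), b, measure="pearson")

    @given(
        st.lists(st.floats(min_value=0.1, max_value=16.0), min_size=4, max_size=12),
        st.lists(st.floats(min_value=0.1, max_value=16.0), min_size=4, max_size=12),
        st.lists(st.floats(min_value=0.1, max_value=16.0), min_size=4, max_size=12),
    )
    @settings(max_examples=300, deadline=None)
    def test_euclidean_is_a_bounded_metric(self, xs, ys, zs):
        t = min(len(xs), len(ys), len(zs))
        x, y, z = np.array(xs[:t]), np.array(ys[:t]), np.array(zs[:t])
        dxy = expression_divergence(x, y)
        dyx = expression_divergence(y, x)
        assert dxy >= 0
        assert dxy == pytest.approx(dyx, rel=1e-12)
        assert dxy <= np.sqrt(2) + 1e-12
        # triangle inequality and zero-iff-equal (on the abundance scale)
        assert dxy <= expression_divergence(x, z) + expression_divergence(z, y) + 1e-9
        if dxy < 1e-12:
            assert np.allclose(relative_abundance(x), relative_abundance(y))


class TestPermutedPairs:
    def test_size_preserved_and_a_members_kept(self, rng):
        pairs = make_pairs(10)
        out = generate_permuted_pairs(pairs, rng)
        assert len(out) == len(pairs)
        assert [p.probeset_a for p in out] == [p.probeset_a for p in pairs]
        assert sorted(p.probeset_b for p in out) == sorted(p.probeset_b for p in pairs)

    def test_seed_reproducible(self):
        pairs = make_pairs(25)
        one = generate_permuted_pairs(pairs, np.random.default_rng(9))
        two = generate_permuted_pairs(pairs, np.random.default_rng(9))
        assert [p.probeset_b for p in one] == [p.probeset_b for p in two]

    def test_too_few_pairs(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            generate_permuted_pairs(make_pairs(1), rng)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t_test([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert t == 0.0 and p == 1.0

    def test_gross_separation(self):
        _, _, p = welch_t_test([1.0, 2, 3, 4], [11.0, 12, 13, 14])
        assert p < 0.01

    def test_textbook_pair_matches_independent_formula(self):
        x = [27.5, 21.0, 19.0, 23.6, 17.0]
        y = [27.1, 22.0, 20.8, 23.4, 23.4]
        t, df, p = welch_t_test(x, y)
        et, edf, ep = oracle_welch(x, y)
        assert t == pytest.approx(et, abs=1e-10)
        assert df == pytest.approx(edf, abs=1e-10)
        assert p == pytest.approx(ep, abs=1e-10)

    def test_degenerate_constant_samples(self):
        t, _, p = welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
        t, _, p = welch_t_test([3.0, 3.0], [2.0, 2.0])
        assert np.isinf(t) and p == 0.0


class TestRunComparison:
    def test_perfect_conservation_degenerate(self, rng):
        A, _ = simulate_profile_pairs(50, 9, alpha=1.0, noise_sd=0.0, rng=rng)
        ma, mb, pairs = paired_matrices(A, A.copy())
        rep = run_divergence_comparison(ma, mb, pairs, rng=1)
        orth = rep.records.query("set_label == 'orthologous'")["divergence"]
        assert (orth == 0).all()
        assert rep.mean_permuted > 0
        assert rep.p_value < 1e-6
        assert rep.n_pairs == len(rep.records.query("set_label == 'permuted'"))

    def test_threshold_choices_agree_on_direction(self, rng):
        A, B = simulate_profile_pairs(800, 9, alpha=0.7, noise_sd=0.4, rng=rng)
        ma, mb, pairs = paired_matrices(A, B)
        outcomes = []
        for thr in (None, 6.5, 8.0):
            rep = run_divergence_comparison(ma, mb, pairs, threshold=thr, rng=5)
            outcomes.append((rep.orthologous_lower, rep.p_value < 0.05))
        assert all(o == (True, True) for o in outcomes)

    def test_filter_can_empty_the_analysis(self, rng):
        A = np.full((5, 9), 5.0)
        ma, mb, pairs = paired_matrices(A, A.copy())
        with pytest.raises(ValueError, match="filter"):
            run_divergence_comparison(ma, mb, pairs, threshold=6.5, rng=0)

    def test_permutation_p_value_detects_conservation(self, rng):
        A, B = simulate_profile_pairs(400, 9, alpha=0.8, noise_sd=0.3, rng=rng)
        ma, mb, pairs = paired_matrices(A, B)
        rep = run_divergence_comparison(ma, mb, pairs, rng=11, n_null_sets=99)
        assert rep.permutation_p == pytest.approx(1 / 100)
        # at alpha=0 the orthologous mean is exchangeable with the null means
        A0, B0 = simulate_profile_pairs(400, 9, alpha=0.0, noise_sd=0.3, rng=rng)
        ma0, mb0, pairs0 = paired_matrices(A0, B0)
        rep0 = run_divergence_comparison(ma0, mb0, pairs0, rng=11, n_null_sets=99)
        assert rep0.permutation_p > 0.05

    def test_report_is_seed_deterministic(self, rng):
        A, B = simulate_profile_pairs(100, 9, alpha=0.5, noise_sd=0.5, rng=rng)
        ma, mb, pairs = paired_matrices(A, B)
        r1 = run_divergence_comparison(ma, mb, pairs, rng=17)
        r2 = run_divergence_comparison(ma, mb, pairs, rng=17)
        assert r1.to_dict() == r2.to_dict()


class TestAlternativeRandomization:
    def test_nonconstant_identical_profiles_diverge_under_shuffle(self, rng):
        A = np.tile(np.array([7.0, 8.0, 9.0, 10.0, 11.0, 7.5, 8.5, 9.5, 10.5]), (20, 1))
        A += rng.normal(0, 0.5, A.shape)
        ma, mb, pairs = paired_matrices(A, A.copy())
        rep = alternative_randomization(ma, mb, pairs, rng=3)
        null = rep.records.query("set_label == 'permuted'")["divergence"]
        assert (null > 0).mean() > 0.9  # a shuffle can be the identity by chance
        assert rep.mean_orthologous == 0.0

    def test_constant_profiles_never_diverge(self):
        A = np.full((5, 9), 8.0)
        ma, mb, pairs = paired_matrices(A, A.copy())
        rep = alternative_randomization(ma, mb, pairs, threshold=None, rng=3)
        assert (rep.records["divergence"] == 0).all()

    def test_agrees_with_permuted_pair_null_on_conserved_data(self, rng):
        A, B = simulate_profile_pairs(600, 9, alpha=0.8, noise_sd=0.3, rng=rng)
        ma, mb, pairs = paired_matrices(A, B)
        r_perm = run_divergence_comparison(ma, mb, pairs, rng=7)
        r_alt = alternative_randomization(ma, mb, pairs, rng=7)
        assert r_perm.orthologous_lower and r_alt.orthologous_lower
        assert r_perm.p_value < 0.05 and r_alt.p_value < 0.05
        assert r_alt.null == "tissue-label-shuffle"


class TestTissueCorrelationMatrix:
    def test_self_pairs_have_unit_diagonal(self, rng):
        A = rng.normal(8, 1, size=(30, 5))
        ma, mb, pairs = paired_matrices(A, A.copy(), tissues=TISSUES9[:5])
        corr = tissue_correlation_matrix(ma, mb, pairs)
        assert np.allclose(np.diag(corr.to_numpy()), 1.0)

    def test_conserved_data_diagonal_dominates(self, rng):
        A, B = simulate_profile_pairs(800, 9, alpha=0.9, noise_sd=0.3, rng=rng)
        ma, mb, pairs = paired_matrices(A, B)
        corr = tissue_correlation_matrix(ma, mb, pairs).to_numpy()
        diag = np.diag(corr).mean()
        off = corr[~np.eye(9, dtype=bool)].mean()
        assert diag > off

    def test_constant_tissue_flagged_not_propagated(self, rng):
        A = rng.normal(8, 1, size=(20, 4))
        B = A.copy()
        B[:, 2] = 5.0  # constant column in species B
        ma, mb, pairs = paired_matrices(A, B, tissues=TISSUES9[:4])
        corr = tissue_correlation_matrix(ma, mb, pairs)
        assert corr.iloc[:, 2].isna().all()
        assert not corr.iloc[:, [0, 1, 3]].isna().any().any()

    def test_too_few_pairs(self, rng):
        A = rng.normal(8, 1, size=(2, 4))
        ma, mb, pairs = paired_matrices(A, A.copy(), tissues=TISSUES9[:4])
        with pytest.raises(ValueError, match="3 pairs"):
            tissue_correlation_matrix(ma, mb, pairs)
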