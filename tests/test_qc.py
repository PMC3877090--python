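"""QC chain tests, each filter against its brute-force oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from inflamsig import (MISSING, SimConfig, exclude_x_chromosome, hwe_exact_test,
                       knn_impute, ld_prune, maf_filter_with_rescue, pca_check,
                       run_qc, sample_call_rate_filter, simulate_cohort,
                       snp_missingness_filter)
from inflamsig.qc import QCError, genotype_r2, pairwise_matching_distance

from conftest import make_genotypes


class TestCallRate:
    def make(self, n_missing):
        codes = np.zeros((2, 100), dtype=np.int8)
        codes[0, :n_missing] = MISSING
        return make_genotypes(codes)

    def test_96_of_100_retained(self):
        G2, stage = sample_call_rate_filter(self.make(4))
        assert G2.n == 2 and stage.n_removed == 0

    def test_95_of_100_removed(self):
        """Retention needs call rate strictly above 0.95."""
        G2, stage = sample_call_rate_filter(self.make(5))
        assert G2.n == 1 and stage.n_removed == 1

    def test_all_removed_is_failure(self):
        codes = np.full((2, 10), MISSING, dtype=np.int8)
        codes[:, 0] = 0
        with pytest.raises(QCError):
            sample_call_rate_filter(make_genotypes(codes))

    def test_removal_fraction_matches_binomial_tail(self):
        """At missing rate 2% over 100 SNPs, P(remove) = P(Bin(100, .98) <= 95)."""
        cfg = SimConfig(n_cases=1500, n_controls=1500, p_snps=100, n_causal=0,
                        missing_rate=0.02, covariate_effects={}, seed=21)
        G, _, _ = simulate_cohort(cfg)
        _, stage = sample_call_rate_filter(G)
        expected = stats.binom.cdf(95, 100, 0.98)
        se = np.sqrt(expected * (1 - expected) / G.n)
        assert abs(stage.n_removed / G.n - expected) < 4 * se + 1e-9


class TestSnpMissingness:
    def test_exactly_5pct_retained_6pct_removed(self):
        codes = np.zeros((100, 2), dtype=np.int8)
        codes[:5, 0] = MISSING
        codes[:6, 1] = MISSING
        G2, stage = snp_missingness_filter(make_genotypes(codes))
        assert list(G2.snps["rs"]) == ["rs0"]
        assert stage.n_removed == 1

    def test_matches_brute_force_recount(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(40, 1000)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.06] = MISSING
        G = make_genotypes(codes)
        G2, _ = snp_missingness_filter(G, 0.05)
        kept_oracle = [j for j in range(1000)
                       if sum(codes[i, j] == MISSING for i in range(40)) / 40 <= 0.05]
        assert list(G2.snps["rs"]) == [f"rs{j}" for j in kept_oracle]


class TestMafRescue:
    def test_common_snp_kept_regardless_of_fisher(self):
        rng = np.random.default_rng(0)
        codes = rng.binomial(2, 0.10, size=(400, 1)).astype(np.int8)
        G = make_genotypes(codes)
        labels = np.repeat([1, 0], 200)
        G2, stage = maf_filter_with_rescue(G, labels)
        assert G2.p == 1 and stage.details["reason"].iloc[0] == "common"

    def test_rare_balanced_snp_removed(self):
        # identical allele counts in cases and controls -> Fisher p = 1
        codes = np.zeros((200, 2), dtype=np.int8)
        codes[:3, 0] = 1    # 3 het cases
        codes[100:103, 0] = 1  # 3 het controls
        codes[::2, 1] = 1   # common companion SNP
        labels = np.repeat([1, 0], 100)
        G2, stage = maf_filter_with_rescue(make_genotypes(codes), labels,
                                           maf_min=0.05)
        assert stage.n_removed == 1
        assert stage.details["reason"].iloc[0] == "rare_no_assoc"
        assert list(G2.snps["rs"]) == ["rs1"]

    def test_rare_associated_snp_rescued(self):
        """Case alleles 10/1990 vs control alleles 1/1999: Fisher p < 0.05."""
        codes = np.zeros((2000, 1), dtype=np.int8)
        codes[:10, 0] = 1       # 10 het cases of 1000
        codes[1000, 0] = 1      # 1 het control of 1000
        labels = np.repeat([1, 0], 1000)
        assert stats.fisher_exact([[10, 1990], [1, 1999]])[1] < 0.05
        G2, stage = maf_filter_with_rescue(make_genotypes(codes), labels)
        assert stage.details["reason"].iloc[0] == "rescued"
        assert G2.p == 1

    def test_monomorphic_removed_with_reason(self):
        codes = np.column_stack([np.zeros(100), np.ones(100) * 0]).astype(np.int8)
        codes[:, 1] = np.tile([0, 1], 50)
        labels = np.repeat([1, 0], 50)
        _, stage = maf_filter_with_rescue(make_genotypes(codes), labels)
        assert stage.details["reason"].iloc[0] == "monomorphic"


class TestKnnImpute:
    def test_modal_neighbor_value(self):
        codes = np.array([
            [1, 0, 1, 1],
            [1, 0, 1, 1],
            [1, 0, 1, 1],
            [1, 0, 1, MISSING],
        ], dtype=np.int8)
        G2 = knn_impute(make_genotypes(codes), k=3)
        assert G2.codes[3, 3] == 1

    def test_duplicate_row_zero_distance(self):
        codes = np.array([
            [0, 1, 2, 0, 2],
            [0, 1, 2, 0, MISSING],
            [2, 2, 0, 1, 0],
            [2, 0, 0, 1, 0],
        ], dtype=np.int8)
        G2 = knn_impute(make_genotypes(codes), k=1)
        assert G2.codes[1, 4] == 2

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(20, 10)).astype(np.int8)
        codes[rng.random(codes.shape) < 0.1] = MISSING
        G = make_genotypes(codes)
        got = knn_impute(G, k=3).codes
        # independent all-pairs reimplementation
        n, p = codes.shape
        expected = codes.copy()
        for i in range(n):
            for j in range(p):
                if codes[i, j] != MISSING:
                    continue
                cand = []
                for h in range(n):
                    if h == i or codes[h, j] == MISSING:
                        continue
                    both = [(codes[i, s], codes[h, s]) for s in range(p)
                            if codes[i, s] != MISSING and codes[h, s] != MISSING]
                    if not both:
                        continue
                    d = 1 - sum(a == b for a, b in both) / len(both)
                    cand.append((d, h))
                cand.sort(key=lambda t: (t[0], t[1]))
                votes = [codes[h, j] for _, h in cand[:3]]
                counts = [votes.count(c) for c in (0, 1, 2)]
                expected[i, j] = int(np.argmax(counts))
        assert np.array_equal(got, expected)

    def test_no_shared_snp_fails(self):
        codes = np.array([[0, MISSING, MISSING],
                          [MISSING, 1, MISSING],
                          [MISSING, 1, 1]], dtype=np.int8)
        with pytest.raises(QCError, match="shares no observed SNP"):
            knn_impute(make_genotypes(codes))

    def test_observed_entries_untouched(self, small_cohort):
        G, _, _ = small_cohort
        obs = G.codes != MISSING
        G2 = knn_impute(G)
        assert np.array_equal(G.codes[obs], G2.codes[obs])
        assert not (G2.codes == MISSING).any()


class TestLdPrune:
    def test_identical_columns_second_dropped(self):
        col = np.tile([0, 1, 2, 1, 0, 2], 5).astype(np.int8)
        G = make_genotypes(np.column_stack([col, col]))
        G2, stage = ld_prune(G)
        assert list(G2.snps["rs"]) == ["rs0"]
        assert stage.details["partner_rs"].iloc[0] == "rs0"

    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(8)
        G = make_genotypes(rng.binomial(2, 0.3, size=(500, 10)).astype(np.int8))
        _, stage = ld_prune(G)
        assert stage.n_removed == 0

    def test_block_structure_surviving_r2_below_threshold(self):
        cfg = SimConfig(n_cases=400, n_controls=400, p_snps=30, n_causal=0,
                        ld_block_size=5, ld_rho=0.97, missing_rate=0.0,
                        covariate_effects={}, seed=13)
        G, _, _ = simulate_cohort(cfg)
        G2, _ = ld_prune(G, 0.8)
        # exhaustive recomputation over all surviving pairs
        X = G2.codes.astype(float)
        for a in range(G2.p):
            for b in range(a + 1, G2.p):
                assert genotype_r2(X[:, a], X[:, b]) <= 0.8
        # idempotence
        G3, stage3 = ld_prune(G2, 0.8)
        assert stage3.n_removed == 0

    def test_constant_snp_treated_as_unlinked(self):
        codes = np.column_stack([
            np.zeros(20), np.tile([0, 1], 10), np.tile([0, 1], 10)]).astype(np.int8)
        G2, stage = ld_prune(make_genotypes(codes))
        assert "rs0" in list(G2.snps["rs"])  # constant column kept, r2 = 0
        assert stage.n_removed == 1


class TestHweExact:
    @staticmethod
    def enumeration_oracle(n_AA, n_Aa, n_aa):
        """Exact rational-arithmetic enumeration over heterozygote counts."""
        n = n_AA + n_Aa + n_aa
        na = n_Aa + 2 * n_aa
        rare = min(na, 2 * n - na)
        probs = {}
        for h in range(rare % 2, rare + 1, 2):
            r_hom = (rare - h) // 2
            c_hom = n - h - r_hom
            probs[h] = (2 ** h * math.factorial(n)
                        // (math.factorial(h) * math.factorial(r_hom)
                            * math.factorial(c_hom)))
        total = sum(probs.values())
        p_obs = probs[n_Aa]
        return sum(v for v in probs.values() if v <= p_obs) / total

    def test_perfect_hwe_is_modal(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_het_deficit(self):
        assert hwe_exact_test(50, 0, 50) < 1e-20

    def test_matches_enumeration_oracle(self):
        for counts in [(57, 78, 15), (10, 10, 10), (100, 50, 3), (5, 0, 5)]:
            assert hwe_exact_test(*counts) == pytest.approx(
                self.enumeration_oracle(*counts), rel=1e-9)

    def test_zero_individuals_fails(self):
        with pytest.raises(ValueError):
            hwe_exact_test(0, 0, 0)

    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40))
    def test_allele_orientation_symmetry_and_range(self, a, b, c):
        if a + b + c == 0:
            return
        p = hwe_exact_test(a, b, c)
        assert 0 < p <= 1 + 1e-12
        assert p == pytest.approx(hwe_exact_test(c, b, a), rel=1e-9)


class TestPca:
    def test_separated_subpopulations(self):
        rng = np.random.default_rng(3)
        X1 = rng.binomial(2, 0.1, size=(60, 40))
        X2 = rng.binomial(2, 0.8, size=(60, 40))
        G = make_genotypes(np.vstack([X1, X2]).astype(np.int8))
        scores = pca_check(G)
        from sklearn.metrics import silhouette_score
        labels = np.repeat([0, 1], 60)
        assert silhouette_score(scores[:, :1], labels) > 0.5

    def test_identical_rows_give_zero_scores(self):
        G = make_genotypes(np.tile([0, 1, 2], (10, 1)).astype(np.int8))
        assert np.allclose(pca_check(G), 0.0)

    def test_components_orthogonal(self, small_cohort):
        G, _, _ = small_cohort
        scores = pca_check(knn_impute(G))
        assert abs(scores[:, 0] @ scores[:, 1]) < 1e-8 * np.linalg.norm(
            scores[:, 0]) * np.linalg.norm(scores[:, 1])


class TestExcludeX:
    def test_autosome_only_unchanged(self):
        G = make_genotypes(np.zeros((3, 4), dtype=np.int8))
        G2, stage = exclude_x_chromosome(G)
        assert G2.p == 4 and stage.n_removed == 0

    def test_x_snps_removed(self):
        chroms = ["1", "X", "2", "X", "X", "3", "4", "5", "6", "7"]
        G = make_genotypes(np.zeros((3, 10), dtype=np.int8), chrom=chroms)
        G2, stage = exclude_x_chromosome(G)
        assert G2.p == 7 and stage.n_removed == 3
        assert not (G2.snps["chrom"] == "X").any()


def test_full_chain_counts_reconcile(small_cohort):
    G, C, _ = small_cohort
    G2, C2, report = run_qc(G, C)
    for stage in report.stages:
        assert stage.n_in - stage.n_removed == stage.n_out
    # sample stages compose to the output n, SNP stages to the output p
    assert report.stages[0].n_out == G2.n == C2.n
    snp_stages = [s for s in report.stages if s.axis == "snps"]
    assert snp_stages[-1].n_out == G2.p
    for prev, nxt in zip(snp_stages, snp_stages[1:]):
        assert prev.n_out == nxt.n_in
    assert not (G2.codes == MISSING).any()


def test_distance_matrix_symmetry(small_cohort):
    G, _, _ = small_cohort
    D = pairwise_matching_distance(G.codes)
    assert np.allclose(D, D.T, equal_nan=True)
    assert np.allclose(np.diag(D), 0.0)
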