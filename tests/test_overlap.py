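"""Overlap counting against brute force; hypergeometric tails against
exhaustive enumeration; sign convention; co-occurrence matrix structure."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chromcode.overlap import (
    cooccurrence_matrix,
    count_overlaps,
    gene_set_overlap,
    hypergeom_signed_ln_p,
    region_set_overlap,
)
from chromcode.trackio import GenomicInterval


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end)


def ln_tail_enumeration(k, K, n, N, upper):
    """Direct pmf enumeration oracle using exact binomial coefficients."""
    denom = math.comb(N, n)
    rng = range(k, min(K, n) + 1) if upper else range(0, k + 1)
    total = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in rng)
    return math.log(total / denom)


class TestCountOverlaps:
    def test_single_shared_bp_counts(self):
        assert count_overlaps([iv(100, 200)], [iv(199, 300)]) == 1

    def test_half_open_abutment_does_not(self):
        assert count_overlaps([iv(100, 200)], [iv(200, 300)]) == 0

    def test_a_counted_once_despite_multiple_hits(self):
        assert count_overlaps([iv(0, 1000)], [iv(10, 20), iv(50, 60)]) == 1

    def test_matches_quadratic_brute_force(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            def random_set(m):
                out = []
                for _ in range(m):
                    s = int(rng.integers(0, 5000))
                    chrom = "chr1" if rng.random() < 0.7 else "chr2"
                    out.append(iv(s, s + int(rng.integers(1, 300)), chrom))
                return out

            a, b = random_set(50), random_set(50)
            brute = sum(any(x.overlaps(y) for y in b) for x in a)
            assert count_overlaps(a, b) == brute
            brute_rev = sum(any(y.overlaps(x) for x in a) for y in b)
            assert count_overlaps(b, a) == brute_rev


class TestHypergeom:
    def test_empty_sets_give_zero(self):
        assert hypergeom_signed_ln_p(0, 0, 0, 20) == 0.0

    def test_small_case_equals_enumeration(self):
        got = hypergeom_signed_ln_p(3, 5, 4, 20)
        assert got == pytest.approx(ln_tail_enumeration(3, 5, 4, 20, upper=True), rel=1e-10)

    def test_identical_sets_maximally_enriched_and_monotone(self):
        vals = [hypergeom_signed_ln_p(K, K, K, 1000) for K in (2, 5, 10, 20)]
        assert all(v < -1 for v in vals)
        assert vals == sorted(vals, reverse=True)  # more overlap, more negative

    def test_depletion_is_positive(self):
        # far fewer overlaps than expected
        assert hypergeom_signed_ln_p(0, 50, 50, 100) > 0

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_signed_ln_p(5, 4, 4, 20)

    def test_tails_equal_enumeration_for_all_small_universes(self):
        for N in range(1, 201, 7):
            K, n = max(N // 3, 1), max(N // 4, 1)
            K, n = min(K, N), min(n, N)
            expected = K * n / N
            support_min = max(0, n + K - N)
            for k in {0, min(K, n), int(expected), min(K, n) // 2}:
                if k < support_min:
                    continue
                got = hypergeom_signed_ln_p(k, K, n, N)
                upper = k >= expected
                oracle = ln_tail_enumeration(k, K, n, N, upper=upper)
                assert got == pytest.approx(
                    oracle if upper else -oracle, rel=1e-9, abs=1e-12
                ), (N, K, n, k)


class TestSignConvention:
    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(1, 500), st.data())
    def test_sign_matches_expectation_side(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n + K - N), min(K, n)))
        value = hypergeom_signed_ln_p(k, K, n, N)
        if k >= K * n / N:
            assert value <= 0  # enrichment side
        else:
            assert value >= 0  # divergence side


class TestGeneSets:
    def test_subset_enrichment_matches_brute_force(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(10)}
        res = gene_set_overlap(a, b, universe)
        assert res.n_overlap == 5
        assert res.signed_ln_p == pytest.approx(
            ln_tail_enumeration(5, 5, 10, 100, upper=True), rel=1e-10
        )

    def test_disjoint_sets_diverge(self):
        universe = {f"g{i}" for i in range(40)}
        a = {f"g{i}" for i in range(15)}
        b = {f"g{i}" for i in range(15, 30)}
        assert gene_set_overlap(a, b, universe).signed_ln_p > 0

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            gene_set_overlap({"x"}, {"y"}, {"y"})

    def test_repressed_genes_enriched_for_hairy_binding(self, benchmark_runs):
        cohort = benchmark_runs[0]["cohort"]
        truth = cohort.truth
        universe = set(truth.labels)
        repressed = {g for g, lab in truth.labels.items() if lab == "repressed"}
        hairy_bound = set(truth.peak_genes["Hairy"])
        res = gene_set_overlap(repressed, hairy_bound, universe)
        assert res.signed_ln_p < -10  # strong enrichment, as planted


class TestCooccurrence:
    def test_matrix_structure(self):
        rng = np.random.default_rng(3)
        base = [iv(int(s), int(s) + 200) for s in rng.integers(0, 100_000, 40)]
        shifted = [iv(x.start + 50, x.end + 50) for x in base]  # overlaps base
        far = [iv(x.start + 500_000, x.end + 500_000) for x in base]
        mat = cooccurrence_matrix(
            {"a_dec": base, "b_dec": shifted, "c_inc": far, "empty": []},
            genome_length=1_000_000,
        )
        assert np.allclose(mat, mat.T)
        # self co-occurrence is the strongest enrichment in the row
        assert mat.loc["a_dec", "a_dec"] == mat.loc["a_dec"].min()
        # co-planted categories enriched; spatially separated ones not
        assert mat.loc["a_dec", "b_dec"] < -5
        assert mat.loc["a_dec", "c_inc"] >= mat.loc["a_dec", "b_dec"]
        assert (mat.loc["empty"] == 0).all()

    def test_needs_two_categories(self):
        with pytest.raises(ValueError):
            cooccurrence_matrix({"only": []}, 1000)

    def test_planted_comarked_decreases_cooccur(self, benchmark_runs):
        run = benchmark_runs[0]
        blocks, cohort = run["blocks"], run["cohort"]
        cats = {
            f"{m}_{d}": [b.interval for b in blocks[m] if b.direction == d]
            for m in ("H4Ac", "H3K27Ac")
            for d in ("decrease", "increase")
        }
        mat = cooccurrence_matrix(cats, cohort.config.genome_length)
        assert mat.loc["H4Ac_decrease", "H3K27Ac_decrease"] < -50
        assert (
            mat.loc["H4Ac_decrease", "H3K27Ac_increase"]
            > mat.loc["H4Ac_decrease", "H3K27Ac_decrease"]
        )
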