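"""SNP QC, permutation HWE (vs an exact enumeration oracle), BH, probe selection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from geqtl import bh_adjust, build_gene_map, hwe_permutation_test, qc_snps, select_probes
from geqtl.preprocess import call_rate, minor_allele_frequency

from conftest import genotypes_from_counts, make_expression, make_genotypes


def exact_hwe_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Enumeration oracle: exact null distribution of the heterozygote count
    under random re-pairing of the observed alleles (Levene-Haldane), with the
    same |het - expected| statistic the permutation test uses."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    p_alt = n_b / (2 * n)
    expected = 2 * n * p_alt * (1 - p_alt)
    stat_obs = abs(n_ab - expected)

    def log_prob(h):
        # P(het = h) for h with the parity of n_a
        a_hom = (n_a - h) // 2
        b_hom = (n_b - h) // 2
        return (
            math.lgamma(n + 1) - math.lgamma(a_hom + 1) - math.lgamma(b_hom + 1)
            - math.lgamma(h + 1) + h * math.log(2)
            + math.lgamma(n_a + 1) + math.lgamma(n_b + 1) - math.lgamma(2 * n + 1)
        )

    total = 0.0
    hit = 0.0
    for h in range(n_a % 2, min(n_a, n_b) + 1, 2):
        pr = math.exp(log_prob(h))
        total += pr
        if abs(h - expected) >= stat_obs - 1e-12:
            hit += pr
    return hit / total


class TestHWEPermutation:
    def test_perfect_hwe_proportions_p_near_one(self):
        g = genotypes_from_counts(25, 50, 25)
        assert hwe_permutation_test(g, n_perm=499, seed=1) >= 0.5

    def test_extreme_heterozygote_excess_rejected(self):
        g = genotypes_from_counts(0, 50, 0)
        assert hwe_permutation_test(g, n_perm=9999, seed=1) < 0.001

    def test_matches_exact_enumeration_oracle(self):
        g = genotypes_from_counts(10, 10, 10)
        p_exact = exact_hwe_p(10, 10, 10)
        p_perm = hwe_permutation_test(g, n_perm=9999, seed=7)
        assert abs(p_perm - p_exact) < 0.02

    def test_monomorphic_warns_p_one(self):
        with pytest.warns(UserWarning, match="monomorphic"):
            assert hwe_permutation_test(np.zeros(20), n_perm=99, seed=0) == 1.0

    def test_type_i_error_under_hwe(self):
        # super-uniformity: empirical alpha at 0.05 within 2 MC s.e. of nominal
        rng = np.random.default_rng(2024)
        n, reps, alpha = 100, 1000, 0.05
        rejections = 0
        for _ in range(reps):
            p = rng.uniform(0.2, 0.8)
            g = rng.binomial(2, p, size=n).astype(float)
            if g.sum() in (0, 2 * n):
                continue
            if hwe_permutation_test(g, n_perm=199, seed=int(rng.integers(2**31))) <= alpha:
                rejections += 1
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert rejections / reps <= alpha + 2 * se


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_matches_brute_force_definition(self, pvals):
        adj = bh_adjust(pvals)
        p = np.asarray(pvals)
        m = p.size
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        for rank_pos, idx in enumerate(order):
            j_range = np.arange(rank_pos, m)
            expected[idx] = min(1.0, np.min(p[order][j_range] * m / (j_range + 1)))
        np.testing.assert_allclose(adj, expected, atol=1e-12)


@pytest.fixture
def qc_annotation():
    return pd.DataFrame(
        {"symbol": ["G1"], "chrom": ["1"], "start": [1], "end": [10_000]},
        index=pd.Index(["G1"], name="gene_id"),
    )


class TestQC:
    def test_low_call_rate_removed(self, qc_annotation):
        # 45 samples, 5 missing -> call rate 40/45 < 0.9
        col = np.ones(45)
        col[:5] = np.nan
        good = np.tile([0.0, 1.0, 2.0], 15)
        gm = make_genotypes(np.column_stack([col, good]), chrom=["1", "1"], pos=[100, 200])
        gmap = build_gene_map(qc_annotation, gm, None)
        kept, report = qc_snps(gm, gmap, hwe_perms=99, seed=0)
        assert report.n_low_call_rate == 1
        assert "snp1" not in kept.snp_ids
        assert call_rate(col) == pytest.approx(40 / 45)

    def test_low_maf_removed(self, qc_annotation):
        # 60 samples: 59 AA + 1 Aa -> MAF 1/120 < 0.01
        rare = np.zeros(60)
        rare[0] = 1.0
        good = np.tile([0.0, 1.0, 2.0], 20)
        gm = make_genotypes(np.column_stack([rare, good]), chrom=["1", "1"], pos=[100, 200])
        gmap = build_gene_map(qc_annotation, gm, None)
        kept, report = qc_snps(gm, gmap, hwe_perms=99, seed=0)
        assert report.n_low_maf == 1
        assert minor_allele_frequency(rare) == pytest.approx(1 / 120)

    def test_clean_snp_retained(self, qc_annotation):
        g = genotypes_from_counts(25, 50, 25)
        gm = make_genotypes(g[:, None], chrom=["1"], pos=[100])
        gmap = build_gene_map(qc_annotation, gm, None)
        kept, report = qc_snps(gm, gmap, hwe_perms=199, seed=0)
        assert kept.snp_ids == ["snp1"]
        assert report.n_retained == 1

    def test_non_autosomal_and_intergenic_removed_in_order(self, qc_annotation):
        good = np.tile([0.0, 1.0, 2.0], 15)
        gm = make_genotypes(
            np.column_stack([good, good, good]),
            chrom=["X", "1", "1"], pos=[100, 200, 99_999],
        )
        gmap = build_gene_map(qc_annotation, gm, None)
        kept, report = qc_snps(gm, gmap, hwe_perms=99, seed=0)
        assert report.n_non_autosomal == 1
        assert report.n_intergenic == 1
        assert kept.snp_ids == ["snp2"]
        assert report.removed_total + report.n_retained == report.n_input

    def test_same_seed_reproducible(self, qc_annotation):
        rng = np.random.default_rng(5)
        vals = rng.binomial(2, 0.4, size=(50, 8)).astype(float)
        gm = make_genotypes(vals, pos=list(range(100, 900, 100)))
        gmap = build_gene_map(qc_annotation, gm, None)
        _, r1 = qc_snps(gm, gmap, hwe_perms=199, seed=11)
        _, r2 = qc_snps(gm, gmap, hwe_perms=199, seed=11)
        pd.testing.assert_frame_equal(r1.stats, r2.stats)


class TestSelectProbes:
    def _expr(self, variances, pop_seed, source=None, chrom=None):
        rng = np.random.default_rng(pop_seed)
        n = 40
        vals = rng.standard_normal((n, len(variances))) * np.sqrt(variances)
        return make_expression(
            vals,
            gene_ids=[f"G{j}" for j in range(len(variances))],
            source=source, chrom=chrom,
        )

    def test_partial_topk_overlap_gives_expected_intersection(self):
        # top-3 sets share exactly probes 0 and 1
        var_a = [100, 90, 80, 1, 1, 1, 1, 1, 1, 1]
        var_b = [100, 90, 1, 80, 1, 1, 1, 1, 1, 1]
        expr = {"P1": self._expr(var_a, 1), "P2": self._expr(var_b, 2)}
        # use exact per-probe variances by overriding with deterministic data
        expr["P1"].values *= 0
        expr["P2"].values *= 0
        for j, v in enumerate(var_a):
            expr["P1"].values[:, j] = np.linspace(0, np.sqrt(v), 40)
        for j, v in enumerate(var_b):
            expr["P2"].values[:, j] = np.linspace(0, np.sqrt(v), 40)
        _, report = select_probes(expr, top_k=3, rank_diff_frac=0.1)
        assert report.set_a == {"probe1", "probe2"}

    def test_source_filter_excludes_gnomon(self):
        source = ["RefSeq"] * 5 + ["Gnomon"] * 5
        expr = {
            "P1": self._expr([10] * 10, 1, source=source),
            "P2": self._expr([10] * 10, 2, source=source),
        }
        final, report = select_probes(expr, top_k=10, allowed_sources={"RefSeq"})
        assert all(expr["P1"].probe_meta.loc[p, "source_db"] == "RefSeq" for p in final)
        assert report.n_removed_source > 0

    def test_non_autosomal_probes_removed(self):
        chrom = ["1"] * 8 + ["X", "Y"]
        expr = {
            "P1": self._expr([10] * 10, 1, chrom=chrom),
            "P2": self._expr([10] * 10, 2, chrom=chrom),
        }
        final, report = select_probes(expr, top_k=10)
        assert report.n_removed_non_autosomal == 2

    def test_population_order_invariance(self):
        expr = {"P1": self._expr(list(range(1, 11)), 1), "P2": self._expr([5] * 10, 2)}
        f1, _ = select_probes(dict(sorted(expr.items())), top_k=4)
        f2, _ = select_probes(dict(sorted(expr.items(), reverse=True)), top_k=4)
        assert f1 == f2

    def test_union_arithmetic(self):
        expr = {"P1": self._expr(list(range(1, 11)), 1), "P2": self._expr([5] * 10, 2)}
        _, report = select_probes(expr, top_k=4)
        assert report.n_union == len(report.set_a | report.set_b)
        assert report.n_union == len(report.set_a) + len(report.set_b) - len(
            report.set_a & report.set_b
        )

    def test_top_k_capped_with_warning(self):
        expr = {"P1": self._expr([5] * 10, 1), "P2": self._expr([5] * 10, 2)}
        with pytest.warns(UserWarning, match="capped"):
            select_probes(expr, top_k=50)
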