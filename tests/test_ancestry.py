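"""Freeman-Halton exact tests, MNM rank test, pharma intersection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from geqtl import (
    ContingencyTable2xK,
    allele_table_from_frequencies,
    allele_table_from_genotypes,
    ancestry_informative_eqtl,
    fisher_exact_2xk,
    intersect_pharma,
    mnm_test,
    resolve_allele_denominator,
)
from geqtl.ancestry import AncestryTestResult, _enumerate_log_probs, _table_log_prob

from conftest import make_genotypes


class TestFreemanHalton:
    def test_2x2_hand_hypergeometric(self):
        # rows (3,1 / 1,3): p = [P(a=3)+P(a=1)+P(a=0)+P(a=4)] with margins 4/4, n=8
        # hand sum: (C(4,3)C(4,1) + C(4,1)C(4,3) + C(4,0)C(4,4) + C(4,4)C(4,0)) / C(8,4)
        tab = ContingencyTable2xK(["a", "b"], np.array([[3, 1], [1, 3]]))
        assert fisher_exact_2xk(tab) == pytest.approx(34 / 70, abs=1e-12)

    def test_proportional_columns_p_one(self):
        tab = ContingencyTable2xK(["a", "b"], np.array([[5, 5], [5, 5]]))
        assert fisher_exact_2xk(tab) == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_2x2(self):
        from scipy.stats import fisher_exact

        rng = np.random.default_rng(3)
        for _ in range(20):
            t = rng.integers(0, 15, size=(2, 2)) + 1
            tab = ContingencyTable2xK(["a", "b"], t)
            ours = fisher_exact_2xk(tab)
            ref = fisher_exact(t, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, rel=1e-8)

    def test_enumeration_probabilities_sum_to_one(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            col = rng.integers(2, 40, size=rng.integers(2, 5))
            r1 = int(rng.integers(1, col.sum()))
            logp = _enumerate_log_probs(col, r1, budget=1e6)
            assert abs(math.exp(logsumexp(logp)) - 1.0) < 1e-9

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(4)
        for seed in range(5):
            t = rng.integers(1, 11, size=(2, 3))
            tab = ContingencyTable2xK(["a", "b", "c"], t)
            p_en = fisher_exact_2xk(tab, method="enumerate")
            p_mc = fisher_exact_2xk(tab, method="monte_carlo", mc_reps=20000, seed=seed)
            se = math.sqrt(max(p_en * (1 - p_en), 1e-6) / 20000)
            assert abs(p_mc - p_en) < 3 * se + 2e-4

    def test_reconstructed_mdr1_table(self):
        # ancestral-allele frequencies 0.892/0.458/0.600/0.511 at 2N=120/120/90/90
        tab = allele_table_from_frequencies(
            [0.892, 0.458, 0.600, 0.511], [120, 120, 90, 90],
            ["YRI", "CEU", "CHB", "JPT"],
        )
        np.testing.assert_array_equal(tab.counts[0], [107, 55, 54, 46])
        p = fisher_exact_2xk(tab)
        assert f"{p:.2E}" == "2.13E-13"

    def test_budget_fallback_warns(self):
        tab = ContingencyTable2xK(
            ["a", "b", "c", "d"], np.array([[50, 50, 50, 50], [50, 50, 50, 50]])
        )
        with pytest.warns(UserWarning, match="monte_carlo"):
            p = fisher_exact_2xk(tab, max_tables=100, mc_reps=2000, seed=0)
        assert 0 < p <= 1


def test_resolve_allele_denominator_unique_match():
    count, denom = resolve_allele_denominator(0.931, 120, max_missing=6)
    assert (count, denom) == (108, 116)


class TestAlleleTables:
    def test_counts_from_genotypes_exclude_missing(self):
        g1 = make_genotypes(np.array([[0.0], [1.0], [2.0], [np.nan]]))
        g2 = make_genotypes(np.array([[2.0], [2.0], [1.0], [1.0]]))
        tab = allele_table_from_genotypes("snp1", {"P1": g1, "P2": g2})
        # P1: 3 called -> 6 alleles, 3 ALT; P2: 8 alleles, 6 ALT
        np.testing.assert_array_equal(tab.counts, [[3, 2], [3, 6]])

    def test_margins_consistent(self):
        tab = ContingencyTable2xK(["a", "b"], np.array([[3, 4], [5, 6]]))
        assert tab.row_margins.tolist() == [7, 11]
        assert tab.col_margins.tolist() == [8, 10]


class TestAncestryInformative:
    def _pops(self, freq1, freq2, n=45, seed=0):
        rng = np.random.default_rng(seed)
        g1 = make_genotypes(rng.binomial(2, freq1, size=(n, len(freq1))).astype(float))
        g2 = make_genotypes(rng.binomial(2, freq2, size=(n, len(freq2))).astype(float))
        return {"P1": g1, "P2": g2}

    def test_fixed_difference_informative(self):
        pops = self._pops([0.0], [1.0])
        res = ancestry_informative_eqtl(["snp1"], pops)
        assert res[0].informative and res[0].p_adjusted < 1e-10

    def test_identical_counts_p_one(self):
        g = make_genotypes(np.tile([0.0, 1.0, 2.0], 15)[:, None])
        res = ancestry_informative_eqtl(["snp1"], {"P1": g, "P2": g})
        assert res[0].p_value == pytest.approx(1.0, abs=1e-9)
        assert not res[0].informative

    def test_fdr_control_under_homogeneous_frequencies(self):
        rng = np.random.default_rng(21)
        n_snps = 200
        freqs = rng.uniform(0.2, 0.8, n_snps)
        pops = self._pops(freqs, freqs, n=45, seed=33)
        res = ancestry_informative_eqtl([f"snp{j+1}" for j in range(n_snps)], pops)
        flagged = sum(r.informative for r in res)
        assert flagged / n_snps <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_snps)

    def test_flagging_monotone_in_alpha(self):
        pops = self._pops([0.1, 0.5, 0.9], [0.9, 0.5, 0.1], seed=5)
        snps = ["snp1", "snp2", "snp3"]
        res_strict = ancestry_informative_eqtl(snps, pops, fdr_alpha=0.01)
        res_loose = ancestry_informative_eqtl(snps, pops, fdr_alpha=0.10)
        strict = {r.marker_id for r in res_strict if r.informative}
        loose = {r.marker_id for r in res_loose if r.informative}
        assert strict <= loose


class TestMNM:
    def test_univariate_equals_kruskal_wallis(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])[:, None]
        labels = np.array([0, 0, 0, 1, 1, 1])
        stat, _ = mnm_test(x, labels)
        assert stat == pytest.approx(3.857142857, abs=1e-9)
        from scipy.stats import kruskal

        h, _ = kruskal(x[:3, 0], x[3:, 0])
        assert stat == pytest.approx(h, abs=1e-9)

    def test_invariant_under_monotone_transform(self, rng):
        X = rng.normal(size=(30, 3))
        labels = np.repeat([0, 1, 2], 10)
        s1, p1 = mnm_test(X, labels)
        X2 = X.copy()
        X2[:, 1] = np.exp(X2[:, 1])  # strictly monotone on one probe
        s2, p2 = mnm_test(X2, labels)
        assert s1 == pytest.approx(s2, abs=1e-10)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_strong_shift_detected(self, rng):
        n = 45
        X = np.vstack([rng.normal(size=(n, 3)), rng.normal(3.0, 1.0, size=(n, 3))])
        labels = np.repeat([0, 1], n)
        _, p = mnm_test(X, labels)
        assert p < 1e-6

    def test_permutation_type_i_error(self):
        rng = np.random.default_rng(55)
        reps, alpha, rejections = 400, 0.05, 0
        for _ in range(reps):
            X = rng.normal(size=(24, 2))
            labels = np.repeat([0, 1], 12)
            _, p = mnm_test(X, labels, mode="permutation", n_perm=99,
                            seed=int(rng.integers(2**31)))
            rejections += p <= alpha
        se = math.sqrt(alpha * (1 - alpha) / reps)
        assert rejections / reps <= alpha + 2 * se

    def test_group_size_validation(self, rng):
        with pytest.raises(ValueError, match=">= 2"):
            mnm_test(rng.normal(size=(5, 2)), np.array([0, 0, 0, 0, 1]))


class TestPharmaIntersect:
    def _results(self, flags):
        tab = ContingencyTable2xK(["a", "b"], np.array([[1, 1], [1, 1]]))
        return [
            AncestryTestResult(rsid, tab, 0.001, 0.01, informative=f)
            for rsid, f in flags.items()
        ]

    def test_inner_join(self):
        res = self._results({"rs1": True, "rs2": True})
        pharma = pd.DataFrame({"rsid": ["rs2"], "category": ["ADR"], "drugs": ["d"]})
        matched, _ = intersect_pharma(res, pharma)
        assert matched["rsid"].tolist() == ["rs2"]
        assert matched["category"].tolist() == ["ADR"]

    def test_non_informative_excluded(self):
        res = self._results({"rs1": False})
        pharma = pd.DataFrame({"rsid": ["rs1"], "category": ["FX"], "drugs": ["d"]})
        matched, _ = intersect_pharma(res, pharma)
        assert len(matched) == 0

    def test_not_interrogated_sidecar(self):
        res = self._results({"rs1": True})
        pharma = pd.DataFrame(
            {"rsid": ["rs1", "rs999"], "category": ["ADR", "FX"], "drugs": ["d", "e"]}
        )
        _, missing = intersect_pharma(res, pharma, genotyped_snps=["rs1"])
        assert missing == ["rs999"]

    def test_duplicate_rsids_deduplicated_with_warning(self):
        res = self._results({"rs1": True})
        pharma = pd.DataFrame(
            {"rsid": ["rs1", "rs1"], "category": ["ADR", "FX"], "drugs": ["d", "e"]}
        )
        with pytest.warns(UserWarning, match="duplicate"):
            matched, _ = intersect_pharma(res, pharma)
        assert matched["rsid"].tolist() == ["rs1"]
        assert matched["category"].tolist() == ["ADR"]


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    a=st.integers(1, 12), b=st.integers(1, 12), c=st.integers(1, 12), d=st.integers(1, 12)
)
def test_observed_table_always_included(a, b, c, d):
    # p >= P(observed); the observed table is always in the tail sum
    tab = ContingencyTable2xK(["x", "y"], np.array([[a, b], [c, d]]))
    p = fisher_exact_2xk(tab)
    assert p >= math.exp(_table_log_prob(tab.counts)) - 1e-12
    assert p <= 1.0 + 1e-12
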