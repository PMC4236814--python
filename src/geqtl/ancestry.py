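"""Ancestry-informativeness tests and pharmacogenetic intersection.

An eQTL is ancestry-informative when its two alleles are differentially
distributed across the K study populations: the 2 x K allele-count table is
tested by the Freeman-Halton exact conditional test (the r x c
generalization of Fisher's 2 x 2 test), with Benjamini-Hochberg FDR across
the tested set.  Ancestry-informative transcripts are detected by a
rank-score multivariate test (a multivariate Kruskal-Wallis) on the probe
block of a T-gene.  Informative eQTL are finally intersected with
pharmacogenetic SNP lists (adverse drug reaction / drug response tables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import chi2, rankdata

from .io import GenotypeMatrix
from .preprocess import bh_adjust

# log-space tie tolerance for "probability <= observed": mathematically tied
# tables reached through different gammaln orderings differ by ~1e-12
_LOG_TIE_TOL = 1e-9


@dataclass
class ContingencyTable2xK:
    """2 x K allele-count table (rows: allele A / allele B; columns: populations)."""

    populations: list[str]
    counts: np.ndarray  # shape (2, K), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, len(self.populations)):
            raise ValueError("counts must be 2 x K matching population labels")
        if len(self.populations) < 2:
            raise ValueError("need K >= 2 populations")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass
class AncestryTestResult:
    marker_id: str
    table: ContingencyTable2xK
    p_value: float
    p_adjusted: float = float("nan")
    informative: bool = False


def _log_binom(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _enumerate_log_probs(col_margins: np.ndarray, r1: int, budget: float):
    """Log-probabilities of all 2 x K tables with the given margins.

    Walks the K-1 free first-row cells by progressive outer products,
    carrying the partial first-row sum; the last cell is determined.
    Returns a flat array of conditional log-probabilities (multivariate
    hypergeometric, margins fixed) or None if the grid exceeds ``budget``.
    """
    K = len(col_margins)
    grid = 1.0
    for nk in col_margins[:-1]:
        grid *= min(int(nk), r1) + 1
    if grid > budget:
        return None
    # partial states: arrays of (first-row partial sum, accumulated log C)
    sums = np.array([0], dtype=np.int64)
    logc = np.array([0.0])
    for nk in col_margins[:-1]:
        a = np.arange(min(int(nk), r1) + 1)
        new_sums = (sums[:, None] + a[None, :]).ravel()
        new_logc = (logc[:, None] + _log_binom(int(nk), a)[None, :]).ravel()
        ok = new_sums <= r1
        sums, logc = new_sums[ok], new_logc[ok]
    last = r1 - sums
    nK = int(col_margins[-1])
    ok = (last >= 0) & (last <= nK)
    logc = logc[ok] + _log_binom(nK, last[ok])
    N = int(col_margins.sum())
    return logc - _log_binom(N, r1)


def _table_log_prob(counts: np.ndarray) -> float:
    col = counts.sum(axis=0)
    r1 = int(counts[0].sum())
    N = int(col.sum())
    return float(_log_binom(col, counts[0]).sum() - _log_binom(N, r1))


def fisher_exact_2xk(
    table: ContingencyTable2xK,
    method: str = "enumerate",
    mc_reps: int = 100_000,
    seed: int | None = None,
    max_tables: float = 5e6,
) -> float:
    """Two-sided Freeman-Halton exact p for a 2 x K table.

    Enumeration sums, in log space, the conditional probabilities of every
    table with the observed margins whose probability is <= the observed
    table's (ties included).  Above ``max_tables`` candidate tables the test
    falls back to Monte Carlo sampling from the conditional null, reporting
    (1 + #{prob <= obs}) / (reps + 1).
    """
    counts = table.counts
    col = table.col_margins
    r1 = int(table.row_margins[0])
    if (col == 0).any():
        raise ValueError("every population must contribute alleles (positive margins)")
    if r1 == 0 or int(table.row_margins[1]) == 0:
        return 1.0  # monomorphic: the observed table is the only one
    log_obs = _table_log_prob(counts)
    if method not in ("enumerate", "monte_carlo"):
        raise ValueError(f"unknown method {method!r}")
    if method == "enumerate":
        logp = _enumerate_log_probs(col, r1, max_tables)
        if logp is None:
            warnings.warn(
                f"enumeration budget exceeded for margins {col.tolist()}; "
                "falling back to monte_carlo"
            )
        else:
            sel = logp <= log_obs + _LOG_TIE_TOL
            return float(min(1.0, np.exp(logsumexp(logp[sel]))))
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col.astype(np.int64), r1, size=mc_reps)
    logp = _log_binom(col[None, :], draws).sum(axis=1) - _log_binom(int(col.sum()), r1)
    hits = int(np.sum(logp <= log_obs + _LOG_TIE_TOL))
    return float((1 + hits) / (mc_reps + 1))


def allele_table_from_genotypes(
    snp_id: str, genotypes_by_pop: dict[str, GenotypeMatrix]
) -> ContingencyTable2xK:
    """2 x K allele counts (A = reference dose 2-g, B = ALT dose g) per population."""
    pops = sorted(genotypes_by_pop)
    counts = np.zeros((2, len(pops)), dtype=np.int64)
    for j, pop in enumerate(pops):
        g = genotypes_by_pop[pop].column(snp_id)
        obs = g[~np.isnan(g)]
        counts[1, j] = int(obs.sum())           # ALT alleles
        counts[0, j] = int(2 * obs.size - counts[1, j])  # reference alleles
    return ContingencyTable2xK(pops, counts)


def allele_table_from_frequencies(
    frequencies, allele_totals, populations=None
) -> ContingencyTable2xK:
    """Reconstruct integer allele counts from per-population frequencies.

    Row A counts are round(freq * 2N); row B the complement.  This mirrors
    how published per-population allele frequencies at fixed sample sizes
    are turned back into a testable table.
    """
    freqs = np.asarray(frequencies, dtype=float)
    tot = np.asarray(allele_totals, dtype=np.int64)
    if populations is None:
        populations = [f"pop{i+1}" for i in range(len(freqs))]
    a = np.rint(freqs * tot).astype(np.int64)
    return ContingencyTable2xK(list(populations), np.vstack([a, tot - a]))


def resolve_allele_denominator(
    frequency: float, full_2n: int, max_missing: int = 6, decimals: int = 3
) -> tuple[int, int]:
    """Find the allele denominator consistent with a printed frequency.

    Searches 2N - m for m = 0..max_missing (missing genotype calls shrink
    the denominator by 2 each, but single-allele dropouts are also allowed)
    and returns the unique (count, denominator) whose rounded ratio matches
    the printed frequency at ``decimals`` places.
    """
    matches = []
    for m in range(max_missing + 1):
        denom = full_2n - m
        count = int(round(frequency * denom))
        if round(count / denom, decimals) == round(frequency, decimals):
            matches.append((count, denom))
    if len(matches) != 1:
        raise ValueError(
            f"frequency {frequency} does not resolve to a unique denominator in "
            f"[{full_2n - max_missing}, {full_2n}]: {matches}"
        )
    return matches[0]


def ancestry_informative_eqtl(
    eqtl_snps,
    genotypes_by_pop: dict[str, GenotypeMatrix],
    fdr_alpha: float = 0.05,
    method: str = "enumerate",
    mc_reps: int = 100_000,
    seed: int | None = None,
) -> list[AncestryTestResult]:
    """Per-SNP Freeman-Halton tests with BH-FDR across the submitted set."""
    snps = sorted(set(eqtl_snps))
    if len(genotypes_by_pop) < 2:
        raise ValueError("need genotypes from >= 2 populations")
    rng = np.random.default_rng(seed)
    results = []
    for snp in snps:
        tab = allele_table_from_genotypes(snp, genotypes_by_pop)
        if (tab.row_margins == 0).any():
            warnings.warn(f"{snp}: monomorphic in all populations; p = 1")
            p = 1.0
        else:
            p = fisher_exact_2xk(
                tab, method=method, mc_reps=mc_reps, seed=int(rng.integers(2**31))
            )
        results.append(AncestryTestResult(snp, tab, p))
    if results:
        adj = bh_adjust([r.p_value for r in results])
        for r, a in zip(results, adj):
            r.p_adjusted = float(a)
            r.informative = bool(a < fdr_alpha)
    return results


def mnm_test(
    T_gene_block,
    group_labels,
    mode: str = "asymptotic",
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Rank-score multivariate test for group differences in a probe block.

    Each probe is mid-ranked across all n samples; with group rank means
    R-bar_g and pooled rank covariance V-hat (denominator n-1),

        W = sum_g n_g (R-bar_g - R-bar)' V-hat^{-1} (R-bar_g - R-bar).

    At t = 1 and no ties W reduces exactly to the Kruskal-Wallis H.
    ``asymptotic`` refers W to chi-square with t(K-1) df; ``permutation``
    shuffles the group labels.  Returns (statistic, p).
    """
    X = np.asarray(T_gene_block, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(group_labels)
    n, t = X.shape
    if labels.shape[0] != n:
        raise ValueError("label length must match sample count")
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 samples")
    R = np.column_stack([rankdata(X[:, j], method="average") for j in range(t)])
    Rbar = R.mean(axis=0)
    V = (R - Rbar).T @ (R - Rbar) / (n - 1)
    try:
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular rank covariance; using pseudo-inverse")
        Vinv = np.linalg.pinv(V)

    def stat(lab):
        w = 0.0
        for g, ng in zip(groups, counts):
            d = R[lab == g].mean(axis=0) - Rbar
            w += ng * float(d @ Vinv @ d)
        return w

    W = stat(labels)
    if mode == "asymptotic":
        df = t * (len(groups) - 1)
        return W, float(chi2.sf(W, df))
    if mode == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if stat(lab) >= W - 1e-12:
                hits += 1
        return W, float((1 + hits) / (n_perm + 1))
    raise ValueError(f"unknown mode {mode!r}")


def intersect_pharma(
    informative: list[AncestryTestResult],
    pharma_list: pd.DataFrame,
    genotyped_snps=None,
    regulated_counts: dict[str, dict[str, int]] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Inner-join ancestry-informative eQTL with a pharmacogenetic SNP list.

    Returns the annotated table and the sidecar list of pharma SNPs absent
    from the genotyping panel ("not interrogated").  ``regulated_counts``
    optionally maps rsid -> {population: number of regulated T-genes}.
    """
    pharma = pharma_list.copy()
    if pharma["rsid"].duplicated().any():
        dups = pharma.loc[pharma["rsid"].duplicated(), "rsid"].tolist()
        warnings.warn(f"duplicate rsIDs in pharma list deduplicated: {dups}")
        pharma = pharma.drop_duplicates(subset="rsid", keep="first")
    by_id = {r.marker_id: r for r in informative}
    rows = []
    for _, prow in pharma.iterrows():
        rsid = prow["rsid"]
        res = by_id.get(rsid)
        if res is None or not res.informative:
            continue
        row = {
            "rsid": rsid,
            "category": prow["category"],
            "drugs": prow.get("drugs", ""),
            "p_value": res.p_value,
            "p_adjusted": res.p_adjusted,
        }
        for pop, cnt in (regulated_counts or {}).get(rsid, {}).items():
            row[f"regulated_t_genes_{pop}"] = cnt
        rows.append(row)
    matched = pd.DataFrame(rows, columns=None if rows else ["rsid", "category", "drugs", "p_value", "p_adjusted"])
    if genotyped_snps is not None:
        panel = set(genotyped_snps)
        not_interrogated = sorted(set(pharma["rsid"]) - panel)
    else:
        not_interrogated = []
    return matched, not_interrogated
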