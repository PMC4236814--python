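"""SNP quality control and expression probe selection.

QC removes SNPs sequentially: non-autosomal, call rate < 0.9, minor allele
frequency < 0.01, permutation-HWE violations at FDR-adjusted p < 0.001, and
finally inter-gene SNPs.  Probe selection combines two lists: the
cross-population intersection of the most variable probes, and the union over
population pairs of probes whose variability ranks differ most; non-RefSeq
and non-autosomal probes are then removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneMap, GenotypeMatrix, is_autosome

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    """Per-step removal tallies and per-SNP QC statistics.

    Steps apply in order: non-autosomal, low call rate, low MAF, HWE
    violation, inter-gene.  ``stats`` holds call rate, MAF and HWE p-values
    (raw and FDR-adjusted) for SNPs reaching each test.
    """

    n_input: int = 0
    n_non_autosomal: int = 0
    n_low_call_rate: int = 0
    n_low_maf: int = 0
    n_hwe_violating: int = 0
    n_intergenic: int = 0
    n_retained: int = 0
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def removed_total(self) -> int:
        return (
            self.n_non_autosomal + self.n_low_call_rate + self.n_low_maf
            + self.n_hwe_violating + self.n_intergenic
        )


def call_rate(column: np.ndarray) -> float:
    return float(np.mean(~np.isnan(column)))


def minor_allele_frequency(column: np.ndarray) -> float:
    """MAF from non-missing additive codes (ALT-allele dose)."""
    obs = column[~np.isnan(column)]
    if obs.size == 0:
        return 0.0
    p_alt = obs.sum() / (2 * obs.size)
    return float(min(p_alt, 1.0 - p_alt))


def hwe_permutation_test(genotypes: np.ndarray, n_perm: int = 999, seed: int | None = None) -> float:
    """Permutation test of Hardy-Weinberg equilibrium on additive codes.

    The statistic is the absolute difference between the observed
    heterozygote count and its expectation under HWE given the allele
    counts.  The null is built by re-pairing the 2N observed alleles into N
    random genotypes; p = (1 + #{perm >= obs}) / (n_perm + 1).
    Monomorphic input cannot depart from HWE: p = 1 with a warning.
    """
    obs = genotypes[~np.isnan(genotypes)].astype(int)
    n = obs.size
    if n < 2:
        raise ValueError("HWE test needs >= 2 non-missing genotypes")
    n_alt = int(obs.sum())
    if n_alt == 0 or n_alt == 2 * n:
        warnings.warn("monomorphic SNP: HWE test not possible, p = 1")
        return 1.0
    p_alt = n_alt / (2 * n)
    expected_het = 2 * n * p_alt * (1 - p_alt)
    obs_het = int(np.sum(obs == 1))
    stat_obs = abs(obs_het - expected_het)

    rng = np.random.default_rng(seed)
    alleles = np.zeros(2 * n, dtype=np.int8)
    alleles[:n_alt] = 1
    # re-pair alleles: each permutation shuffles the 2N alleles and pairs
    # consecutive entries; heterozygote iff the pair differs
    perms = np.tile(alleles, (n_perm, 1))
    perms = rng.permuted(perms, axis=1)
    het_counts = np.sum(perms[:, 0::2] != perms[:, 1::2], axis=1)
    stats = np.abs(het_counts - expected_het)
    return float((1 + np.sum(stats >= stat_obs - 1e-12)) / (n_perm + 1))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def qc_snps(
    genotypes: GenotypeMatrix,
    gene_map: GeneMap | None = None,
    call_rate_min: float = 0.9,
    maf_min: float = 0.01,
    hwe_alpha: float = 0.001,
    hwe_perms: int = 999,
    seed: int | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Sequential SNP QC for one population; returns survivors and a report."""
    report = QCReport(n_input=genotypes.n_snps)
    meta = genotypes.snp_meta
    keep = list(genotypes.snp_ids)

    # 1. non-autosomal
    if "chrom" in meta.columns:
        autosomal = [s for s in keep if is_autosome(meta.loc[s, "chrom"])]
    else:
        autosomal = keep
    report.n_non_autosomal = len(keep) - len(autosomal)
    keep = autosomal

    cols = {s: genotypes.column(s) for s in keep}

    # 2. call rate
    cr = {s: call_rate(cols[s]) for s in keep}
    survivors = [s for s in keep if cr[s] >= call_rate_min]
    report.n_low_call_rate = len(keep) - len(survivors)
    keep = survivors

    # 3. MAF
    maf = {s: minor_allele_frequency(cols[s]) for s in keep}
    survivors = [s for s in keep if maf[s] >= maf_min]
    report.n_low_maf = len(keep) - len(survivors)
    keep = survivors

    # 4. permutation HWE with BH-FDR across SNPs surviving the MAF filter
    rng = np.random.default_rng(seed)
    hwe_p = {}
    for s in keep:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hwe_p[s] = hwe_permutation_test(
                cols[s], n_perm=hwe_perms, seed=int(rng.integers(2**31))
            )
    if keep:
        adj = bh_adjust([hwe_p[s] for s in keep])
        hwe_adj = dict(zip(keep, adj))
        survivors = [s for s in keep if hwe_adj[s] >= hwe_alpha]
    else:
        hwe_adj = {}
        survivors = []
    report.n_hwe_violating = len(keep) - len(survivors)
    keep = survivors

    # 5. inter-gene
    if gene_map is not None:
        survivors = [s for s in keep if gene_map.snp_to_genes.get(s)]
        report.n_intergenic = len(keep) - len(survivors)
        keep = survivors

    report.n_retained = len(keep)
    report.stats = pd.DataFrame(
        {
            "call_rate": pd.Series(cr),
            "maf": pd.Series(maf),
            "hwe_p": pd.Series(hwe_p),
            "hwe_p_adj": pd.Series(hwe_adj),
        }
    )
    report.stats.index.name = "snp_id"
    if not keep:
        warnings.warn("no SNPs survived QC; returning empty matrix")
        return GenotypeMatrix(genotypes.sample_ids, [], np.empty((genotypes.n_samples, 0))), report
    return genotypes.subset_snps(keep), report


@dataclass
class ProbeSelectionReport:
    """Tallies from the two-list probe selection."""

    variability: pd.DataFrame = field(default_factory=pd.DataFrame)  # probe x population
    set_a: set = field(default_factory=set)  # variability-intersection list
    set_b: set = field(default_factory=set)  # rank-difference union list
    n_union: int = 0
    n_removed_source: int = 0
    n_removed_non_autosomal: int = 0
    final: set = field(default_factory=set)


def _top_k_by_variance(var: pd.Series, k: int) -> set:
    order = var.sort_values(ascending=False, kind="mergesort")
    return set(order.index[:k])


def select_probes(
    expr_by_pop: dict[str, ExpressionMatrix],
    top_k: int,
    rank_diff_frac: float = 0.01,
    allowed_sources: set[str] | None = None,
    autosomes_only: bool = True,
    variability: str = "variance",
) -> tuple[set, ProbeSelectionReport]:
    """Two-list probe selection across populations.

    List A intersects each population's ``top_k`` most variable probes; list
    B unions, over population pairs, the top ``rank_diff_frac`` of probes by
    absolute difference of variability ranks (ties at the boundary all
    included).  The final set is (A | B) restricted to ``allowed_sources``
    and, optionally, autosomes.
    """
    if allowed_sources is None:
        allowed_sources = {"RefSeq"}
    pops = sorted(expr_by_pop)
    if len(pops) < 2:
        raise ValueError("select_probes needs >= 2 populations")
    universe = expr_by_pop[pops[0]].probe_ids
    for p in pops[1:]:
        if expr_by_pop[p].probe_ids != universe:
            raise ValueError("probe universe differs across populations")
    n_probes = len(universe)
    if top_k > n_probes:
        warnings.warn(f"top_k={top_k} exceeds {n_probes} probes; capped")
        top_k = n_probes

    if variability == "variance":
        stat = lambda v: np.var(v, axis=0, ddof=1)  # noqa: E731
    elif variability == "iqr":
        stat = lambda v: np.subtract(*np.percentile(v, [75, 25], axis=0))  # noqa: E731
    else:
        raise ValueError(f"unknown variability statistic {variability!r}")

    var = pd.DataFrame(
        {p: stat(expr_by_pop[p].values) for p in pops}, index=pd.Index(universe, name="probe_id")
    )

    set_a = _top_k_by_variance(var[pops[0]], top_k)
    for p in pops[1:]:
        set_a &= _top_k_by_variance(var[p], top_k)

    # mid-ranks of variability per population (rank 1 = least variable;
    # direction cancels in the absolute difference)
    ranks = {p: rankdata(var[p].to_numpy(), method="average") for p in pops}
    n_top = max(1, int(np.ceil(rank_diff_frac * n_probes)))
    set_b: set = set()
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            diff = np.abs(ranks[pops[i]] - ranks[pops[j]])
            # include all probes tied with the n_top-th largest difference
            threshold = np.sort(diff)[::-1][n_top - 1]
            set_b |= {universe[k] for k in np.nonzero(diff >= threshold)[0]}

    union = set_a | set_b
    report = ProbeSelectionReport(variability=var, set_a=set_a, set_b=set_b, n_union=len(union))

    meta = expr_by_pop[pops[0]].probe_meta
    final = set(union)
    if "source_db" in meta.columns:
        bad_src = {p for p in final if meta.loc[p, "source_db"] not in allowed_sources}
        report.n_removed_source = len(bad_src)
        final -= bad_src
    if autosomes_only and "chrom" in meta.columns:
        bad_chr = {
            p for p in final
            if pd.isna(meta.loc[p, "chrom"]) or not is_autosome(meta.loc[p, "chrom"])
        }
        report.n_removed_non_autosomal = len(bad_chr)
        final -= bad_chr
    report.final = final
    return final, report
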