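"""Genome scan driver: gene-based and SNP-based eQTL calling.

For each (S-gene, T-gene) pair the SNP block is regressed on the transcript
block by gene-based PLS; the factor count is chosen by 7-fold cross-validated
PRESS plus van der Voet's test, and the pair is called an eQTL when the
final model keeps at least one factor and explains a non-zero share of both
blocks.  A call is cis when S-gene and T-gene are the same gene, trans
otherwise.  SNP-based (s-eQTL) mapping is the single-SNP special case.
"""

from __future__ import annotations

import logging
import os
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneMap, GenotypeMatrix
from .model_select import cv_press
from .pls import GeneBlockPLS, impute_missing

logger = logging.getLogger(__name__)


@dataclass
class ScanConfig:
    """Thresholds and seeds for eQTL calling."""

    k_folds: int = 7
    fold_scheme: str = "interleaved"
    max_factors: int | None = None
    vdv_randomizations: int = 2000
    vdv_alpha: float = 0.10
    epsilon: float = 1e-8  # "non-zero variation" floor, fraction of block variance
    seed: int = 0


@dataclass
class EQTLRecord:
    population: str
    s_gene: str
    snp_ids: list[str]
    t_gene: str
    probe_ids: list[str]
    n_factors: int
    canonical_correlation: float
    explained_s: float
    explained_t: float
    regulation: str  # "cis" | "trans"

    def __post_init__(self) -> None:
        if self.regulation not in ("cis", "trans"):
            raise ValueError(f"regulation must be cis/trans, got {self.regulation!r}")
        expected = "cis" if self.s_gene == self.t_gene else "trans"
        if self.regulation != expected:
            raise ValueError("cis/trans flag inconsistent with gene ids")
        if self.n_factors < 1:
            raise ValueError("an eQTL record requires >= 1 extracted factor")


def call_pair(
    S_gene_block,
    T_gene_block,
    s_gene: str,
    t_gene: str,
    snp_ids: list[str],
    probe_ids: list[str],
    population: str = "ALL",
    config: ScanConfig | None = None,
):
    """Run model selection + final fit on one pair; record or None.

    Returns ``(record_or_None, press_curve_or_None)``.
    """
    config = config or ScanConfig()
    S = impute_missing(np.asarray(S_gene_block, dtype=float), snp_ids)
    T = np.asarray(T_gene_block, dtype=float)
    if T.ndim == 1:
        T = T[:, None]
    if np.all(S.std(axis=0) == 0) or np.all(T.std(axis=0) == 0):
        warnings.warn(f"degenerate block for pair ({s_gene}, {t_gene}); skipped")
        return None, None
    seed = _pair_seed(config.seed, s_gene, t_gene)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        curve = cv_press(
            S, T,
            max_factors=config.max_factors,
            k_folds=config.k_folds,
            fold_scheme=config.fold_scheme,
            seed=seed,
            n_randomizations=config.vdv_randomizations,
            alpha=config.vdv_alpha,
        )
    r_sel = curve.selected
    if r_sel < 1:
        return None, curve
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = GeneBlockPLS(n_factors=r_sel).fit(S, T)
    if model.n_factors_ < 1:
        return None, curve
    ex_s = float(model.explained_x_ratio_.sum())
    ex_t = float(model.explained_y_ratio_.sum())
    if min(ex_s, ex_t) <= config.epsilon:
        return None, curve
    record = EQTLRecord(
        population=population,
        s_gene=s_gene,
        snp_ids=list(snp_ids),
        t_gene=t_gene,
        probe_ids=list(probe_ids),
        n_factors=model.n_factors_,
        canonical_correlation=model.canonical_correlation(0),
        explained_s=ex_s,
        explained_t=ex_t,
        regulation="cis" if s_gene == t_gene else "trans",
    )
    return record, curve


def call_seqtl(
    snp_column,
    T_gene_block,
    snp_id: str,
    s_gene: str,
    t_gene: str,
    probe_ids: list[str],
    population: str = "ALL",
    config: ScanConfig | None = None,
):
    """SNP-based eQTL call: the single-SNP special case of call_pair."""
    col = np.asarray(snp_column, dtype=float).reshape(-1, 1)
    obs = col[~np.isnan(col)]
    if obs.size == 0 or obs.std() == 0:
        warnings.warn(f"monomorphic or empty SNP column {snp_id}; skipped")
        return None, None
    return call_pair(
        col, T_gene_block, s_gene, t_gene, [snp_id], probe_ids, population, config
    )


def _pair_seed(base_seed: int, s_gene: str, t_gene: str) -> int:
    """Deterministic per-pair seed independent of scan order and process."""
    h = zlib.crc32(f"{s_gene}|{t_gene}".encode()) & 0x7FFFFFFF
    return int((base_seed * 1_000_003 + h) % (2**31 - 1))


def _resolve_pairs(gene_map: GeneMap, mode: str, pair_filter) -> list[tuple[str, str]]:
    s_genes = sorted({g for gs in gene_map.snp_to_genes.values() for g in gs})
    t_genes = sorted(set(gene_map.probe_to_gene.values()))
    if isinstance(pair_filter, (list, tuple, set)):
        return sorted(set(pair_filter))
    if pair_filter == "cis_only":
        return [(g, g) for g in s_genes if g in set(t_genes)]
    if isinstance(pair_filter, dict) and "chromosomes" in pair_filter:
        chroms = {str(c) for c in pair_filter["chromosomes"]}
        s_genes = [g for g in s_genes if str(gene_map.genes.loc[g, "chrom"]) in chroms]
        t_genes = [g for g in t_genes if str(gene_map.genes.loc[g, "chrom"]) in chroms]
        return [(s, t) for s in s_genes for t in t_genes]
    if pair_filter == "all":
        n_pairs = len(s_genes) * len(t_genes)
        if n_pairs > 10_000:
            raise ValueError(
                f"all-pairs scan would attempt {n_pairs} pairs; pass an explicit "
                "pair filter (cis_only, chromosome subset, or pair list) at this scale"
            )
        return [(s, t) for s in s_genes for t in t_genes]
    raise ValueError(f"unknown pair filter {pair_filter!r}")


def genome_scan(
    genotypes: GenotypeMatrix,
    expression: ExpressionMatrix,
    gene_map: GeneMap,
    mode: str = "gene_based",
    pair_filter="all",
    population: str = "ALL",
    config: ScanConfig | None = None,
    checkpoint: str | None = None,
) -> tuple[list[EQTLRecord], pd.DataFrame]:
    """Scan S-gene x T-gene pairs (or SNP x T-gene in snp_based mode).

    Output ordering is deterministic (sorted by S-gene id then T-gene id).
    With ``checkpoint`` set, completed pair keys are appended to that file
    and skipped on rerun.
    """
    if mode not in ("gene_based", "snp_based"):
        raise ValueError(f"mode must be gene_based or snp_based, got {mode!r}")
    config = config or ScanConfig()
    g_set, e_set = set(genotypes.sample_ids), set(expression.sample_ids)
    if g_set != e_set:
        raise ValueError(
            f"sample sets differ between matrices; offenders: {sorted(g_set ^ e_set)[:10]}"
        )
    # canonical sample order makes results invariant to input row permutation
    order = sorted(genotypes.sample_ids)
    if genotypes.sample_ids != order:
        genotypes = genotypes.subset_samples(order)
    if expression.sample_ids != order:
        expression = expression.subset_samples(order)
    done: set[str] = set()
    done_records: list[EQTLRecord] = []
    if checkpoint and os.path.exists(checkpoint):
        ck = pd.read_csv(checkpoint, sep="\t", dtype=str)
        done = set(ck["key"])
        for _, row in ck.iterrows():
            if row["called"] == "1":
                done_records.append(
                    EQTLRecord(
                        population=row["population"],
                        s_gene=row["s_gene"],
                        snp_ids=row["snp_ids"].split(","),
                        t_gene=row["t_gene"],
                        probe_ids=row["probe_ids"].split(","),
                        n_factors=int(row["n_factors"]),
                        canonical_correlation=float(row["canonical_correlation"]),
                        explained_s=float(row["explained_s"]),
                        explained_t=float(row["explained_t"]),
                        regulation=row["regulation"],
                    )
                )

    pairs = _resolve_pairs(gene_map, mode, pair_filter)
    records: list[EQTLRecord] = list(done_records)
    press_rows = []
    ck_fh = None
    if checkpoint:
        new_file = not os.path.exists(checkpoint)
        ck_fh = open(checkpoint, "a")
        if new_file:
            ck_fh.write(
                "key\tcalled\tpopulation\ts_gene\tsnp_ids\tt_gene\tprobe_ids\t"
                "n_factors\tcanonical_correlation\texplained_s\texplained_t\tregulation\n"
            )
    try:
        for s_gene, t_gene in pairs:
            snp_ids = gene_map.snps_of_gene(s_gene)
            snp_ids = [s for s in snp_ids if s in set(genotypes.snp_ids)]
            probe_ids = [p for p in gene_map.probes_of_gene(t_gene) if p in set(expression.probe_ids)]
            if not snp_ids or not probe_ids:
                continue
            T = expression.subset_probes(probe_ids).values
            units = (
                [(s_gene, snp_ids)] if mode == "gene_based" else [(snp, [snp]) for snp in snp_ids]
            )
            for unit_label, unit_snps in units:
                key = f"{unit_label}|{t_gene}"
                if key in done:
                    continue
                S = genotypes.subset_snps(unit_snps).values
                if mode == "snp_based":
                    rec, curve = call_seqtl(
                        S[:, 0], T, unit_snps[0], s_gene, t_gene, probe_ids, population, config
                    )
                else:
                    rec, curve = call_pair(
                        S, T, s_gene, t_gene, unit_snps, probe_ids, population, config
                    )
                if curve is not None:
                    for r, rmp in zip(curve.factor_counts, curve.root_mean_press):
                        press_rows.append(
                            {
                                "s_unit": unit_label,
                                "t_gene": t_gene,
                                "n_factors": int(r),
                                "root_mean_press": float(rmp),
                                "p_value": curve.p_values.get(int(r), np.nan),
                            }
                        )
                if rec is not None:
                    records.append(rec)
                if ck_fh is not None:
                    if rec is None:
                        ck_fh.write(f"{key}\t0\t{population}\t{s_gene}\t\t{t_gene}\t\t0\t0\t0\t0\ttrans\n")
                    else:
                        ck_fh.write(
                            f"{key}\t1\t{rec.population}\t{rec.s_gene}\t{','.join(rec.snp_ids)}\t"
                            f"{rec.t_gene}\t{','.join(rec.probe_ids)}\t{rec.n_factors}\t"
                            f"{rec.canonical_correlation}\t{rec.explained_s}\t{rec.explained_t}\t"
                            f"{rec.regulation}\n"
                        )
                    ck_fh.flush()
    finally:
        if ck_fh is not None:
            ck_fh.close()
    records.sort(key=lambda r: (r.s_gene, r.t_gene, r.snp_ids))
    press_log = pd.DataFrame(
        press_rows, columns=["s_unit", "t_gene", "n_factors", "root_mean_press", "p_value"]
    )
    return records, press_log


def records_to_frame(records: list[EQTLRecord]) -> pd.DataFrame:
    rows = [
        {
            "population": r.population,
            "s_gene": r.s_gene,
            "snp_ids": ",".join(r.snp_ids),
            "t_gene": r.t_gene,
            "probe_ids": ",".join(r.probe_ids),
            "n_factors": r.n_factors,
            "canonical_correlation": r.canonical_correlation,
            "explained_s": r.explained_s,
            "explained_t": r.explained_t,
            "regulation": r.regulation,
        }
        for r in records
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "population", "s_gene", "snp_ids", "t_gene", "probe_ids", "n_factors",
            "canonical_correlation", "explained_s", "explained_t", "regulation",
        ],
    )
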