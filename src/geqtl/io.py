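"""Readers, writers and core containers for genotype/expression eQTL data.

Genotypes are held as additive ALT-allele counts (0, 1, 2) with NaN as the
missing sentinel; expression as real-valued sample x probe matrices.  Gene
annotation drives both the SNP -> gene assignment that defines S-gene blocks
and the probe -> gene assignment that defines T-gene blocks.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = np.nan

_AUTOSOMES = {str(i) for i in range(1, 23)}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading 'chr' prefix so annotation dialects interoperate."""
    c = str(chrom).strip()
    return c[3:] if c.lower().startswith("chr") else c


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) in _AUTOSOMES


@dataclass
class GenotypeMatrix:
    """Sample x SNP additive genotype codes.

    ``values`` is an ``n x s`` float array with entries in {0, 1, 2} or NaN
    for missing calls.  ``snp_meta`` is indexed by SNP id and carries
    ``chrom`` (normalized, no 'chr' prefix), ``pos`` (1-based), and optional
    ``alleleA`` / ``alleleB`` columns.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray
    snp_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"genotype matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        observed = self.values[~np.isnan(self.values)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise ValueError(f"genotype codes outside {{0,1,2,NA}}: {bad[:5]}")
        if len(self.snp_meta) == 0:
            self.snp_meta = pd.DataFrame(index=pd.Index(self.snp_ids, name="snp_id"))
        if "pos" in self.snp_meta.columns:
            pos = self.snp_meta["pos"].dropna()
            if (pos < 1).any():
                raise ValueError("SNP positions must be >= 1 (1-based)")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def subset_snps(self, snp_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.snp_ids.index(s) for s in snp_ids]
        meta = self.snp_meta.loc[snp_ids] if len(self.snp_meta) else self.snp_meta
        return GenotypeMatrix(self.sample_ids, list(snp_ids), self.values[:, idx], meta)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.snp_ids, self.values[idx, :], self.snp_meta)

    def column(self, snp_id: str) -> np.ndarray:
        return self.values[:, self.snp_ids.index(snp_id)]


@dataclass
class ExpressionMatrix:
    """Sample x probe expression values with per-probe annotation.

    ``probe_meta`` is indexed by probe id with columns ``gene_id``, ``chrom``
    and ``source_db`` (e.g. RefSeq / UniGene / Gnomon).
    """

    sample_ids: list[str]
    probe_ids: list[str]
    values: np.ndarray
    probe_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probe_ids)):
            raise ValueError(
                f"expression matrix shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.probe_ids)} probes"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("expression values must be finite")
        if len(self.probe_meta) == 0:
            self.probe_meta = pd.DataFrame(index=pd.Index(self.probe_ids, name="probe_id"))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    def subset_probes(self, probe_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        meta = self.probe_meta.loc[probe_ids] if len(self.probe_meta) else self.probe_meta
        return ExpressionMatrix(self.sample_ids, list(probe_ids), self.values[:, idx], meta)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(sample_ids), self.probe_ids, self.values[idx, :], self.probe_meta)


@dataclass
class GeneMap:
    """Gene coordinates plus SNP->genes and probe->gene assignments.

    A SNP overlapping several gene intervals is assigned to all of them;
    SNPs mapping to no gene are flagged inter-gene.  Probes citing a gene id
    absent from the annotation are collected in ``unmapped_probes``.
    """

    genes: pd.DataFrame  # index gene_id; columns symbol, chrom, start, end
    snp_to_genes: dict[str, set[str]]
    probe_to_gene: dict[str, str]
    intergenic_snps: set[str] = field(default_factory=set)
    unmapped_probes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.genes) and (self.genes["start"] > self.genes["end"]).any():
            bad = self.genes[self.genes["start"] > self.genes["end"]].index.tolist()
            raise ValueError(f"gene interval with start > end: {bad}")

    def snps_of_gene(self, gene_id: str) -> list[str]:
        return sorted(s for s, gs in self.snp_to_genes.items() if gene_id in gs)

    def probes_of_gene(self, gene_id: str) -> list[str]:
        return sorted(p for p, g in self.probe_to_gene.items() if g == gene_id)


def read_genotypes_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic GT records from a VCF into additive ALT-allele codes.

    Multi-allelic records and records lacking GT are skipped with a logged
    warning count.  Missing genotypes become NaN.
    """
    from cyvcf2 import VCF

    try:
        # gts012: gt_types coded 0=hom-ref, 1=het, 2=hom-alt, 3=unknown
        vcf = VCF(path, gts012=True)
    except Exception as exc:  # unreadable / malformed container
        raise IOError(f"cannot read VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows = []
    meta = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_skipped += 1
            continue
        gts = var.gt_types
        if gts is None or len(gts) != len(samples):
            n_skipped += 1
            continue
        codes = np.array([0.0, 1.0, 2.0, np.nan])[np.asarray(gts)]
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        snp_ids.append(vid)
        rows.append(codes)
        meta.append(
            {
                "snp_id": vid,
                "chrom": normalize_chrom(var.CHROM),
                "pos": int(var.POS),
                "alleleA": var.REF,
                "alleleB": var.ALT[0],
            }
        )
    if n_skipped:
        logger.warning("skipped %d multi-allelic or GT-less VCF records", n_skipped)
    values = np.column_stack(rows) if rows else np.empty((len(samples), 0))
    snp_meta = pd.DataFrame(meta).set_index("snp_id") if meta else pd.DataFrame()
    gm = GenotypeMatrix(samples, snp_ids, values, snp_meta)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def read_matrix_tsv(path: str, kind: str):
    """Read a sample x marker TSV (header = marker ids, first column = sample id).

    ``kind`` selects validation: 'genotype' enforces {0,1,2,NA} codes,
    'expression' enforces finite reals.
    """
    if kind not in ("genotype", "expression"):
        raise ValueError(f"kind must be 'genotype' or 'expression', got {kind!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: no data rows") from exc
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    sample_ids = [str(s) for s in df.index]
    marker_ids = [str(c) for c in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for the error message
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df.iloc[:, j]):
                if pd.isna(v):
                    continue
                try:
                    float(v)
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric value {v!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    if kind == "genotype":
        observed = values[~np.isnan(values)]
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            ii, jj = np.nonzero(~np.isnan(values))
            k = np.nonzero(bad)[0][0]
            raise ValueError(
                f"{path}: genotype code {observed[bad][0]!r} outside {{0,1,2,NA}} at "
                f"row {sample_ids[ii[k]]!r}, column {marker_ids[jj[k]]!r}"
            )
        return GenotypeMatrix(sample_ids, marker_ids, values)
    if np.isnan(values).any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return ExpressionMatrix(sample_ids, marker_ids, values)


def write_matrix_tsv(matrix, path: str) -> None:
    """Write a GenotypeMatrix or ExpressionMatrix in the layout read_matrix_tsv expects."""
    ids = matrix.snp_ids if isinstance(matrix, GenotypeMatrix) else matrix.probe_ids
    vals = matrix.values
    if isinstance(matrix, GenotypeMatrix):
        col_fmt = lambda v: "NA" if np.isnan(v) else str(int(v))  # noqa: E731
    else:
        col_fmt = lambda v: repr(float(v))  # noqa: E731
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(matrix.sample_ids):
            fh.write(sid + "\t" + "\t".join(col_fmt(v) for v in vals[i]) + "\n")


def read_gene_annotation(path: str) -> pd.DataFrame:
    """Gene annotation TSV: gene_id, symbol, chrom, start, end (1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str, "chrom": str})
    required = {"gene_id", "symbol", "chrom", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: annotation missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.set_index("gene_id")


def read_probe_map(path: str) -> pd.DataFrame:
    """Probe map TSV: probe_id, gene_id, chrom, source_db."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probe_id", "gene_id", "chrom", "source_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: probe map missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df.set_index("probe_id")


def read_snp_map(path: str) -> pd.DataFrame:
    """SNP annotation TSV: snp_id, chrom, pos (1-based), optional alleles."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    required = {"snp_id", "chrom", "pos"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: SNP map missing columns {sorted(missing)}")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int)
    return df.set_index("snp_id")


def read_pharma_list(path: str) -> pd.DataFrame:
    """Pharmacogenetic SNP list TSV: rsid, category in {ADR, FX, both}, drugs free text."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "rsid" not in df.columns or "category" not in df.columns:
        raise ValueError(f"{path}: pharma list needs 'rsid' and 'category' columns")
    bad = set(df["category"]) - {"ADR", "FX", "both"}
    if bad:
        raise ValueError(f"{path}: unknown pharma categories {sorted(bad)}")
    return df


def build_gene_map(
    annotation: pd.DataFrame,
    genotypes: GenotypeMatrix | None = None,
    expression: ExpressionMatrix | None = None,
    flank: int = 0,
) -> GeneMap:
    """Assign SNPs to genes by physical position and probes to genes by annotation.

    A SNP is assigned to every gene whose [start-flank, end+flank] interval
    contains its position on the same chromosome; a SNP overlapping no gene
    is flagged inter-gene.  Probes citing gene ids absent from the annotation
    are flagged unmapped (non-fatal).
    """
    snp_to_genes: dict[str, set[str]] = {}
    intergenic: set[str] = set()
    if genotypes is not None and len(genotypes.snp_meta):
        by_chrom: dict[str, pd.DataFrame] = {
            str(c): sub for c, sub in annotation.groupby("chrom")
        }
        for snp_id in genotypes.snp_ids:
            row = genotypes.snp_meta.loc[snp_id]
            chrom = normalize_chrom(row.get("chrom", ""))
            pos = row.get("pos", np.nan)
            hits: set[str] = set()
            sub = by_chrom.get(chrom)
            if sub is not None and not pd.isna(pos):
                inside = (sub["start"] - flank <= pos) & (pos <= sub["end"] + flank)
                hits = set(sub.index[inside])
            if hits:
                snp_to_genes[snp_id] = hits
            else:
                intergenic.add(snp_id)
    probe_to_gene: dict[str, str] = {}
    unmapped: set[str] = set()
    if expression is not None and len(expression.probe_meta):
        for probe_id in expression.probe_ids:
            gid = expression.probe_meta.loc[probe_id].get("gene_id")
            if isinstance(gid, str) and "," in gid:
                parts = [g.strip() for g in gid.split(",")]
                logger.warning("probe %s lists %d genes; using first (%s)", probe_id, len(parts), parts[0])
                gid = parts[0]
            if gid is None or pd.isna(gid) or gid not in annotation.index:
                unmapped.add(probe_id)
            else:
                probe_to_gene[probe_id] = str(gid)
    return GeneMap(annotation, snp_to_genes, probe_to_gene, intergenic, unmapped)


def write_eqtl_archive(records, out_dir: str) -> dict[str, dict[str, str]]:
    """Write the three-table eQTL results archive, one file set per population.

    Tables: per-T-gene (cis flag, comma-separated trans regulators), the
    symmetric per-S-gene table, and a per-SNP table.  Availability and cis
    columns use "1" / "NA".
    Returns {population: {table name: path}}.
    """
    os.makedirs(out_dir, exist_ok=True)
    by_pop: dict[str, list] = {}
    for r in records:
        by_pop.setdefault(r.population, []).append(r)
    paths: dict[str, dict[str, str]] = {}
    for pop in sorted(by_pop) or []:
        recs = by_pop[pop]
        tgenes: dict[str, dict] = {}
        sgenes: dict[str, dict] = {}
        snps: list[dict] = []
        for r in recs:
            t = tgenes.setdefault(r.t_gene, {"cis": "NA", "trans": []})
            s = sgenes.setdefault(r.s_gene, {"cis": "NA", "trans": []})
            if r.regulation == "cis":
                t["cis"] = "1"
                s["cis"] = "1"
            else:
                t["trans"].append(r.s_gene)
                s["trans"].append(r.t_gene)
            for snp in r.snp_ids:
                snps.append(
                    {
                        "snp_id": snp,
                        "s_gene": r.s_gene,
                        "t_gene": r.t_gene,
                        "regulation": r.regulation,
                        "n_factors": r.n_factors,
                        "canonical_correlation": r.canonical_correlation,
                    }
                )
        pop_paths = {}
        tpath = os.path.join(out_dir, f"{pop}_t_genes.tsv")
        with open(tpath, "w") as fh:
            fh.write("t_gene\tavailable\tcis\ttrans_s_genes\n")
            for g in sorted(tgenes):
                trans = ",".join(sorted(set(tgenes[g]["trans"])))
                fh.write(f"{g}\t1\t{tgenes[g]['cis']}\t{trans if trans else 'NA'}\n")
        spath = os.path.join(out_dir, f"{pop}_s_genes.tsv")
        with open(spath, "w") as fh:
            fh.write("s_gene\tavailable\tcis\ttrans_t_genes\n")
            for g in sorted(sgenes):
                trans = ",".join(sorted(set(sgenes[g]["trans"])))
                fh.write(f"{g}\t1\t{sgenes[g]['cis']}\t{trans if trans else 'NA'}\n")
        epath = os.path.join(out_dir, f"{pop}_eqtl.tsv")
        pd.DataFrame(
            snps,
            columns=[
                "snp_id", "s_gene", "t_gene", "regulation", "n_factors",
                "canonical_correlation",
            ],
        ).to_csv(epath, sep="\t", index=False)
        pop_paths.update({"t_genes": tpath, "s_genes": spath, "eqtl": epath})
        paths[pop] = pop_paths
    if not by_pop:
        # headers-only files under a generic label so downstream globs succeed
        for name, header in (
            ("all_t_genes.tsv", "t_gene\tavailable\tcis\ttrans_s_genes\n"),
            ("all_s_genes.tsv", "s_gene\tavailable\tcis\ttrans_t_genes\n"),
            ("all_eqtl.tsv", "snp_id\ts_gene\tt_gene\tregulation\tn_factors\tcanonical_correlation\n"),
        ):
            with open(os.path.join(out_dir, name), "w") as fh:
                fh.write(header)
    return paths
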