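"""Synthetic multi-population genotype and expression data with planted eQTL.

Genotypes follow the Balding-Nichols model: each SNP draws an ancestral
frequency p ~ Uniform(0.1, 0.9) and each population draws its own frequency
from Beta(p(1-F)/F, (1-p)(1-F)/F) — F is the FST-like divergence — then
genotypes are Binomial(2, p_pop) (Hardy-Weinberg sampling within
populations).  Expression probes are mu + sum_j beta_j g_j + Gaussian noise
for planted (S-gene, T-gene) effects and pure noise otherwise.  Gene
coordinates are laid out deterministically so the derived GeneMap is always
consistent with the matrices.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneMap,
    GenotypeMatrix,
    build_gene_map,
    write_matrix_tsv,
)


@dataclass
class PlantedEffect:
    s_gene: str
    t_gene: str
    betas: np.ndarray  # per-SNP effect sizes, length = SNPs per S-gene
    cis: bool = False


@dataclass
class SimulationConfig:
    """Study-condition parameters for the generator.

    Defaults mirror a two-population, desk-scale version of a four-population
    lymphoblastoid eQTL study: 45 samples per population, divergence F = 0.01
    for neutral SNPs and 0.2 for ancestry-informative ones, Gaussian
    expression noise sigma = 1.
    """

    populations: dict[str, int] = field(default_factory=lambda: {"POP1": 45, "POP2": 45})
    n_genes: int = 10
    snps_per_gene: int = 4
    probes_per_gene: int = 3
    f_neutral: float = 0.01
    f_aim: float = 0.2
    n_aim_snps: int = 0
    aim_delta: float | None = None  # deterministic frequency split for AIM SNPs
    planted_effects: list[PlantedEffect] = field(default_factory=list)
    noise_sigma: float = 1.0
    baseline_mu: float = 8.0
    missing_rate: float = 0.0
    ld_rho: float = 0.0  # optional within-gene correlation of latent gametes
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.populations.values()):
            raise ValueError("every population needs >= 2 samples")
        for f in (self.f_neutral, self.f_aim):
            if not 0 <= f < 1:
                raise ValueError("divergence F must lie in [0, 1)")
        if self.noise_sigma <= 0:
            raise ValueError("noise sigma must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must lie in [0, 1)")
        gene_ids = {f"G{i+1}" for i in range(self.n_genes)}
        for eff in self.planted_effects:
            if eff.s_gene not in gene_ids or eff.t_gene not in gene_ids:
                raise ValueError(f"planted effect references unknown gene: {eff}")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i+1}" for i in range(self.n_genes)]


def _gene_layout(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic coordinates: genes cycle over autosomes, 10 kb apart."""
    rows = []
    span = 1000 * config.snps_per_gene
    for i, gid in enumerate(config.gene_ids):
        chrom = str((i % 22) + 1)
        start = 10_000 + (i // 22) * (span + 10_000)
        rows.append(
            {"gene_id": gid, "symbol": gid, "chrom": chrom, "start": start, "end": start + span}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def simulate_genotypes(config: SimulationConfig):
    """Per-population genotype matrices plus the frequency truth table.

    Returns (dict population -> GenotypeMatrix, annotation DataFrame,
    truth DataFrame with ancestral and per-population frequencies).
    """
    rng = np.random.default_rng(config.seed)
    annotation = _gene_layout(config)
    pops = list(config.populations)
    snp_ids, metas = [], []
    n_snps = config.n_genes * config.snps_per_gene
    p_anc = rng.uniform(0.1, 0.9, size=n_snps)
    is_aim = np.zeros(n_snps, dtype=bool)
    if config.n_aim_snps:
        is_aim[rng.choice(n_snps, size=config.n_aim_snps, replace=False)] = True
    # per-population frequencies
    pop_freq = {}
    for pi, pop in enumerate(pops):
        f_vec = np.where(is_aim, config.f_aim, config.f_neutral)
        freq = np.empty(n_snps)
        for j in range(n_snps):
            F = f_vec[j]
            if config.aim_delta is not None and is_aim[j]:
                # deterministic split: alternate populations sit at p +/- delta/2
                sign = 1 if pi % 2 == 0 else -1
                freq[j] = np.clip(p_anc[j] + sign * config.aim_delta / 2, 0.02, 0.98)
            elif F == 0:
                freq[j] = p_anc[j]
            else:
                a = p_anc[j] * (1 - F) / F
                b = (1 - p_anc[j]) * (1 - F) / F
                freq[j] = rng.beta(a, b)
        pop_freq[pop] = freq
    k = 0
    for i, gid in enumerate(config.gene_ids):
        g = annotation.loc[gid]
        for j in range(config.snps_per_gene):
            sid = f"{gid}_snp{j+1}"
            snp_ids.append(sid)
            metas.append(
                {
                    "snp_id": sid,
                    "chrom": g["chrom"],
                    "pos": int(g["start"]) + 500 + 1000 * j,
                    "alleleA": "A",
                    "alleleB": "B",
                    "aim": bool(is_aim[k]),
                }
            )
            k += 1
    snp_meta = pd.DataFrame(metas).set_index("snp_id")
    genotypes = {}
    for pop in pops:
        n = config.populations[pop]
        freq = pop_freq[pop]
        if config.ld_rho > 0:
            # correlated latent gametes within each gene (AR(1) on a latent normal)
            from scipy.stats import norm

            vals = np.empty((n, n_snps))
            thresh = norm.ppf(freq)
            for gi in range(config.n_genes):
                sl = slice(gi * config.snps_per_gene, (gi + 1) * config.snps_per_gene)
                m = sl.stop - sl.start
                cov = config.ld_rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
                L = np.linalg.cholesky(cov)
                for hap in range(2):
                    z = rng.standard_normal((n, m)) @ L.T
                    alleles = (z < thresh[sl]).astype(float)
                    if hap == 0:
                        vals[:, sl] = alleles
                    else:
                        vals[:, sl] += alleles
        else:
            vals = rng.binomial(2, freq[None, :], size=(n, n_snps)).astype(float)
        if config.missing_rate > 0:
            mask = rng.random(vals.shape) < config.missing_rate
            vals[mask] = np.nan
        sample_ids = [f"{pop}_{i+1:03d}" for i in range(n)]
        genotypes[pop] = GenotypeMatrix(sample_ids, list(snp_ids), vals, snp_meta.copy())
    truth = pd.DataFrame(
        {"p_ancestral": p_anc, "aim": is_aim, **{f"p_{p}": pop_freq[p] for p in pops}},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return genotypes, annotation.reset_index(), truth


def simulate_expression(genotypes: dict[str, GenotypeMatrix], config: SimulationConfig):
    """Expression matrices with planted linear SNP effects plus Gaussian noise.

    Returns (dict population -> ExpressionMatrix, probe map DataFrame,
    truth DataFrame of planted pairs).
    """
    rng = np.random.default_rng(config.seed + 1)
    probe_rows = []
    annotation = _gene_layout(config)
    for gid in config.gene_ids:
        for j in range(config.probes_per_gene):
            probe_rows.append(
                {
                    "probe_id": f"{gid}_probe{j+1}",
                    "gene_id": gid,
                    "chrom": annotation.loc[gid, "chrom"],
                    "source_db": "RefSeq",
                }
            )
    probe_map = pd.DataFrame(probe_rows).set_index("probe_id")
    probe_ids = list(probe_map.index)
    effects_by_t: dict[str, list[PlantedEffect]] = {}
    for eff in config.planted_effects:
        effects_by_t.setdefault(eff.t_gene, []).append(eff)
    expr = {}
    for pop, gm in genotypes.items():
        n = gm.n_samples
        vals = config.baseline_mu + rng.normal(0, config.noise_sigma, size=(n, len(probe_ids)))
        for t_gene, effs in effects_by_t.items():
            cols = [j for j, p in enumerate(probe_ids) if probe_map.loc[p, "gene_id"] == t_gene]
            for eff in effs:
                snps = [f"{eff.s_gene}_snp{j+1}" for j in range(config.snps_per_gene)]
                G = np.stack([gm.column(s) for s in snps], axis=1)
                G = np.where(np.isnan(G), np.nanmean(G, axis=0), G)
                signal = G @ np.asarray(eff.betas, dtype=float)
                for c in cols:
                    vals[:, c] += signal
        expr[pop] = ExpressionMatrix(gm.sample_ids, probe_ids, vals, probe_map.copy())
    truth = pd.DataFrame(
        [
            {"s_gene": e.s_gene, "t_gene": e.t_gene, "cis": e.s_gene == e.t_gene,
             "betas": ",".join(str(b) for b in np.asarray(e.betas).ravel())}
            for e in config.planted_effects
        ],
        columns=["s_gene", "t_gene", "cis", "betas"],
    )
    return expr, probe_map.reset_index(), truth


def gene_map_for(config: SimulationConfig, genotypes: GenotypeMatrix, expression: ExpressionMatrix) -> GeneMap:
    annotation = _gene_layout(config)
    return build_gene_map(annotation, genotypes, expression)


def _concat_pops(mats: dict):
    first = next(iter(mats.values()))
    sample_ids = [s for m in mats.values() for s in m.sample_ids]
    values = np.vstack([m.values for m in mats.values()])
    if isinstance(first, GenotypeMatrix):
        return GenotypeMatrix(sample_ids, first.snp_ids, values, first.snp_meta)
    return ExpressionMatrix(sample_ids, first.probe_ids, values, first.probe_meta)


TINY = SimulationConfig(
    populations={"POP1": 23, "POP2": 22},
    n_genes=43,
    snps_per_gene=28,
    probes_per_gene=4,
    n_aim_snps=10,
    aim_delta=0.4,
    planted_effects=[],  # filled per-seed in make_fixture_dataset
)

PAPER_LIKE = SimulationConfig(
    populations={"YRI": 60, "CEU": 60, "CHB": 45, "JPT": 45},
    n_genes=43,
    snps_per_gene=28,
    probes_per_gene=4,
    n_aim_snps=20,
    aim_delta=0.4,
)


def make_fixture_dataset(profile: str, out_dir: str, seed: int = 0, force: bool = False) -> dict:
    """Write a complete on-disk fixture bundle (all TSV).

    tiny: 45 samples in two populations, 43 S-genes x 28 SNPs (1204 SNP
    columns), 7 of the genes carry 4 transcript probes each (45 x 28
    expression cells), with two planted cis pairs and one trans pair.
    paper_like: the four-population variant (60/60/45/45 samples).
    """
    import dataclasses

    if profile not in ("tiny", "paper_like"):
        raise ValueError(f"unknown profile {profile!r}")
    if os.path.exists(out_dir) and os.listdir(out_dir) and not force:
        raise FileExistsError(f"{out_dir} exists and is non-empty; pass force=True")
    os.makedirs(out_dir, exist_ok=True)
    base = TINY if profile == "tiny" else PAPER_LIKE
    betas = np.zeros(base.snps_per_gene)
    betas[:2] = 1.0
    config = dataclasses.replace(
        base,
        seed=seed,
        planted_effects=[
            PlantedEffect("G1", "G1", betas, cis=True),
            PlantedEffect("G2", "G2", betas, cis=True),
            PlantedEffect("G8", "G3", betas, cis=False),
        ],
    )
    genotypes, annotation, geno_truth = simulate_genotypes(config)
    expr_all, probe_map, expr_truth = simulate_expression(genotypes, config)
    # only the first 7 genes carry transcript probes (T-genes)
    t_genes = config.gene_ids[:7]
    keep_probes = [p for p in probe_map["probe_id"] if p.rsplit("_", 1)[0] in t_genes]
    expr_all = {pop: m.subset_probes(keep_probes) for pop, m in expr_all.items()}
    probe_map = probe_map[probe_map["probe_id"].isin(keep_probes)]

    geno = _concat_pops(genotypes)
    expr = _concat_pops(expr_all)
    paths = {}
    paths["genotypes"] = os.path.join(out_dir, "genotypes.tsv")
    write_matrix_tsv(geno, paths["genotypes"])
    paths["expression"] = os.path.join(out_dir, "expression.tsv")
    write_matrix_tsv(expr, paths["expression"])
    paths["annotation"] = os.path.join(out_dir, "genes.tsv")
    annotation.to_csv(paths["annotation"], sep="\t", index=False)
    paths["snp_map"] = os.path.join(out_dir, "snps.tsv")
    geno.snp_meta[["chrom", "pos"]].to_csv(paths["snp_map"], sep="\t")
    paths["probe_map"] = os.path.join(out_dir, "probes.tsv")
    probe_map.to_csv(paths["probe_map"], sep="\t", index=False)
    paths["populations"] = os.path.join(out_dir, "populations.tsv")
    pd.DataFrame(
        [(s, pop) for pop, m in genotypes.items() for s in m.sample_ids],
        columns=["sample_id", "population"],
    ).to_csv(paths["populations"], sep="\t", index=False)
    paths["pharma"] = os.path.join(out_dir, "pharma.tsv")
    aim_snps = geno_truth.index[geno_truth["aim"]].tolist()
    pharma_rows = [
        {"rsid": aim_snps[0], "category": "ADR", "drugs": "drugA"},
        {"rsid": aim_snps[1] if len(aim_snps) > 1 else aim_snps[0], "category": "FX", "drugs": "drugB"},
        {"rsid": "rs0000000", "category": "both", "drugs": "drugC"},  # not interrogated
    ]
    pd.DataFrame(pharma_rows).drop_duplicates(subset="rsid").to_csv(
        paths["pharma"], sep="\t", index=False
    )
    paths["truth_genotypes"] = os.path.join(out_dir, "truth_genotypes.tsv")
    geno_truth.to_csv(paths["truth_genotypes"], sep="\t")
    paths["truth_effects"] = os.path.join(out_dir, "truth_effects.tsv")
    expr_truth.to_csv(paths["truth_effects"], sep="\t", index=False)
    return paths
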