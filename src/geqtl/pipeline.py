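"""End-to-end driver: QC -> probe selection -> per-population eQTL scan ->
ancestry tests -> pharmacogenetic intersection -> ancestry classifier.

A run is fully determined by its ``RunConfig`` (paths, thresholds, seeds);
the manifest written next to the outputs records the config hash, per-stage
status and the package version so any output is reproducible from the
manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .ancestry import ancestry_informative_eqtl, intersect_pharma, mnm_test
from .classify import nested_cv_classify
from .eqtl import ScanConfig, genome_scan, records_to_frame
from .io import (
    build_gene_map,
    read_gene_annotation,
    read_matrix_tsv,
    read_pharma_list,
    read_probe_map,
    read_snp_map,
    write_eqtl_archive,
)
from .preprocess import bh_adjust, qc_snps, select_probes

logger = logging.getLogger(__name__)

STAGES = ["qc", "probe_selection", "scan", "ancestry_tests", "pharma_intersect", "classify"]


@dataclass
class RunConfig:
    """All inputs, thresholds and seeds of one pipeline run."""

    genotypes: str = ""
    expression: str = ""
    annotation: str = ""
    probe_map: str = ""
    snp_map: str = ""
    populations: str = ""  # TSV sample_id -> population
    pharma: str | None = None
    out_dir: str = "geqtl_out"
    call_rate_min: float = 0.9
    maf_min: float = 0.01
    hwe_alpha: float = 0.001
    hwe_perms: int = 499
    fdr_alpha: float = 0.05
    vdv_alpha: float = 0.10
    vdv_randomizations: int = 2000
    stop_delta: float = 0.001
    k_folds_press: int = 7
    k_folds_classify: int = 10
    top_k_probes: int = 0  # 0 = keep all probes (skip variability filter)
    rank_diff_frac: float = 0.01
    pair_filter: str = "all"
    scan_mode: str = "gene_based"
    classify_set: str = "union"
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("call_rate_min", 0, 1), ("maf_min", 0, 0.5), ("hwe_alpha", 0, 1),
            ("fdr_alpha", 0, 1), ("vdv_alpha", 0, 1), ("stop_delta", 0, 1),
            ("rank_diff_frac", 0, 1),
        ):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.k_folds_press < 2 or self.k_folds_classify < 2:
            raise ValueError("fold counts must be >= 2")

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the manifest dict (also written to disk)."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {s: "pending" for s in STAGES},
        "timings": {},
    }

    def _finish(stage, t0):
        manifest["stages"][stage] = "complete"
        manifest["timings"][stage] = round(time.time() - t0, 3)

    try:
        genotypes = read_matrix_tsv(config.genotypes, "genotype")
        expression = read_matrix_tsv(config.expression, "expression")
        annotation = read_gene_annotation(config.annotation)
        probe_map = read_probe_map(config.probe_map)
        pop_df = pd.read_csv(config.populations, sep="\t", dtype=str)
        pop_of = dict(zip(pop_df["sample_id"], pop_df["population"]))
        missing = [s for s in genotypes.sample_ids if s not in pop_of]
        if missing:
            raise ValueError(f"samples without population label: {missing[:10]}")
        expression.probe_meta = probe_map.loc[expression.probe_ids]
        if config.snp_map:
            snp_meta = read_snp_map(config.snp_map)
            genotypes.snp_meta = snp_meta.loc[genotypes.snp_ids]
        pops = sorted(set(pop_of.values()))
        by_pop_samples = {
            p: [s for s in genotypes.sample_ids if pop_of[s] == p] for p in pops
        }

        # stage 1: per-population SNP QC
        t0 = time.time()
        gene_map_full = build_gene_map(annotation, genotypes, expression)
        geno_by_pop = {}
        qc_rows = []
        rng = np.random.default_rng(config.seed)
        for p in pops:
            gpop = genotypes.subset_samples(by_pop_samples[p])
            gq, rep = qc_snps(
                gpop, gene_map_full,
                call_rate_min=config.call_rate_min, maf_min=config.maf_min,
                hwe_alpha=config.hwe_alpha, hwe_perms=config.hwe_perms,
                seed=int(rng.integers(2**31)),
            )
            geno_by_pop[p] = gq
            qc_rows.append(
                {
                    "population": p, "input": rep.n_input,
                    "non_autosomal": rep.n_non_autosomal,
                    "low_call_rate": rep.n_low_call_rate, "low_maf": rep.n_low_maf,
                    "hwe_violating": rep.n_hwe_violating,
                    "intergenic": rep.n_intergenic, "retained": rep.n_retained,
                }
            )
            logger.info("QC %s: %d -> %d SNPs", p, rep.n_input, rep.n_retained)
        pd.DataFrame(qc_rows).to_csv(
            os.path.join(config.out_dir, "qc_report.tsv"), sep="\t", index=False
        )
        _finish("qc", t0)

        # stage 2: probe selection across populations
        t0 = time.time()
        expr_by_pop = {p: expression.subset_samples(by_pop_samples[p]) for p in pops}
        if config.top_k_probes > 0 and len(pops) >= 2:
            selected, rep = select_probes(
                expr_by_pop, top_k=config.top_k_probes,
                rank_diff_frac=config.rank_diff_frac,
            )
            keep = [p for p in expression.probe_ids if p in selected]
        else:
            keep = [
                p for p in expression.probe_ids
                if probe_map.loc[p, "source_db"] == "RefSeq"
            ]
        expr_by_pop = {p: m.subset_probes(keep) for p, m in expr_by_pop.items()}
        _finish("probe_selection", t0)

        # stage 3: per-population genome scan
        t0 = time.time()
        all_records = []
        scan_cfg = ScanConfig(
            k_folds=config.k_folds_press,
            vdv_randomizations=config.vdv_randomizations,
            vdv_alpha=config.vdv_alpha,
            seed=config.seed,
        )
        for p in pops:
            gmap = build_gene_map(annotation, geno_by_pop[p], expr_by_pop[p])
            records, press = genome_scan(
                geno_by_pop[p], expr_by_pop[p], gmap,
                mode=config.scan_mode, pair_filter=config.pair_filter,
                population=p, config=scan_cfg,
            )
            all_records.extend(records)
            press.to_csv(
                os.path.join(config.out_dir, f"press_{p}.tsv"), sep="\t", index=False
            )
        records_to_frame(all_records).to_csv(
            os.path.join(config.out_dir, "eqtl_records.tsv"), sep="\t", index=False
        )
        write_eqtl_archive(all_records, os.path.join(config.out_dir, "archive"))
        _finish("scan", t0)

        # stage 4: ancestry-informative eQTL and transcripts
        t0 = time.time()
        eqtl_snps = sorted({s for r in all_records for s in r.snp_ids})
        shared = set(geno_by_pop[pops[0]].snp_ids)
        for p in pops[1:]:
            shared &= set(geno_by_pop[p].snp_ids)
        testable = [s for s in eqtl_snps if s in shared]
        results = (
            ancestry_informative_eqtl(
                testable, geno_by_pop, fdr_alpha=config.fdr_alpha, seed=config.seed
            )
            if len(pops) >= 2 and testable
            else []
        )
        pd.DataFrame(
            [
                {
                    "snp_id": r.marker_id, "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted, "informative": r.informative,
                }
                for r in results
            ],
            columns=["snp_id", "p_value", "p_adjusted", "informative"],
        ).to_csv(os.path.join(config.out_dir, "ancestry_eqtl.tsv"), sep="\t", index=False)

        # ancestry-informative transcripts (MNM per T-gene)
        labels = np.concatenate([[p] * len(by_pop_samples[p]) for p in pops])
        expr_all_rows = np.vstack([expr_by_pop[p].values for p in pops])
        probe_ids = expr_by_pop[pops[0]].probe_ids
        t_genes = sorted({probe_map.loc[pr, "gene_id"] for pr in probe_ids})
        mnm_rows = []
        if len(pops) >= 2:
            for tg in t_genes:
                cols = [i for i, pr in enumerate(probe_ids) if probe_map.loc[pr, "gene_id"] == tg]
                stat, pval = mnm_test(expr_all_rows[:, cols], labels, mode="asymptotic")
                mnm_rows.append({"t_gene": tg, "statistic": stat, "p_value": pval})
        mnm_df = pd.DataFrame(mnm_rows, columns=["t_gene", "statistic", "p_value"])
        if len(mnm_df):
            mnm_df["p_adjusted"] = bh_adjust(mnm_df["p_value"].to_numpy())
            mnm_df["informative"] = mnm_df["p_adjusted"] < config.fdr_alpha
        mnm_df.to_csv(os.path.join(config.out_dir, "ancestry_transcripts.tsv"), sep="\t", index=False)
        _finish("ancestry_tests", t0)

        # stage 5: pharmacogenetic intersection
        t0 = time.time()
        if config.pharma:
            pharma = read_pharma_list(config.pharma)
            matched, not_interrogated = intersect_pharma(
                results, pharma, genotyped_snps=genotypes.snp_ids
            )
            matched.to_csv(
                os.path.join(config.out_dir, "pharma_informative.tsv"), sep="\t", index=False
            )
            with open(os.path.join(config.out_dir, "pharma_not_interrogated.tsv"), "w") as fh:
                fh.write("rsid\n")
                for r in not_interrogated:
                    fh.write(r + "\n")
        _finish("pharma_intersect", t0)

        # stage 6: ancestry-predictive panel from informative eQTL genotypes
        t0 = time.time()
        informative_snps = [r.marker_id for r in results if r.informative]
        panel_out = {"selected": [], "test_accuracy": None}
        if len(pops) >= 2 and informative_snps:
            X = np.vstack(
                [geno_by_pop[p].subset_snps(informative_snps).values for p in pops]
            )
            X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
            y = labels
            panel = nested_cv_classify(
                X, y, snp_ids=informative_snps, k=min(config.k_folds_classify, min(
                    len(by_pop_samples[p]) for p in pops)),
                seed=config.seed, stop_delta=config.stop_delta,
            )
            panel_out = {
                "selected": panel.snp_ids,
                "test_accuracy": panel.best_test_accuracy,
                "fold_test_accuracy": panel.fold_test_accuracy,
                "chosen_fold": panel.chosen_fold,
            }
        with open(os.path.join(config.out_dir, "classifier_panel.json"), "w") as fh:
            json.dump(panel_out, fh, indent=2)
        _finish("classify", t0)
    except Exception as exc:
        failed = [s for s in STAGES if manifest["stages"][s] == "pending"]
        if failed:
            manifest["stages"][failed[0]] = f"failed: {exc}"
        manifest["error"] = str(exc)
        with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
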