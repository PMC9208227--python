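"""End-to-end pipeline: simulate -> QC -> map-cis -> map-interaction -> summarize.

Each stage writes TSV outputs into the run directory and appends to a
machine-readable manifest (seeds, input checksums, filter counts). Stage
seeds are derived from the master seed by adding the CRC-32 of the stage
name (mod 2^31), so any stage can be rerun in isolation and reproduce the
full-pipeline behavior.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import preprocess, stats
from .cis import map_cis, somqtl_test
from .datatypes import ExpressionSet, GenotypeMatrix, SomaticTable
from .interaction import map_interaction
from .synthdata import CohortData, SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]

STAGES = ("simulate", "qc_genotypes", "qc_expression", "map_cis", "map_interaction",
          "summarize")


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: (master seed + CRC-32 of the stage name) mod 2^31."""
    return (master_seed + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All pipeline thresholds plus the simulation parameters.

    Defaults follow common tumor-eQTL practice: MAF >= 0.01, sample
    missingness <= 2.5%, 5 genotype PCs, 15 hidden expression factors,
    gene filter 0.1 TPM and 6 reads in >= 20% of samples, +/- 1 Mb cis
    window, minor allele count >= 5, 1,000-10,000 adaptive permutations,
    eGene FDR 0.05, ieGene FDR 0.10, tertile alpha 0.05, downsampling to
    200 patients.
    """

    out_dir: str = "caneqtl_run"
    seed: int = 0
    sim: dict = field(default_factory=dict)
    maf_min: float = 0.01
    snp_missing_max: float = 0.95
    sample_missing_max: float = 0.025
    r2_min: float = 0.3
    n_genotype_pcs: int = 5
    n_hidden_factors: int = 15
    tpm_min: float = 0.1
    count_min: int = 6
    frac_min: float = 0.20
    outlier_pcs: int = 6
    outlier_sd: float = 3.0
    window: int = 1_000_000
    mac_min: int = 5
    n_perm_min: int = 1000
    n_perm_max: int = 10_000
    egene_fdr: float = 0.05
    iegene_fdr: float = 0.10
    tertile_alpha: float = 0.05
    downsample_n: int = 200

    def sim_config(self) -> SimConfig:
        sim = dict(self.sim)
        sim.setdefault("seed", stage_seed(self.seed, "simulate"))
        if "maf_range" in sim:
            sim["maf_range"] = tuple(sim["maf_range"])
        return SimConfig(**sim)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory.

    Reruns with an identical config produce byte-identical result TSVs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {s: stage_seed(cfg.seed, s) for s in STAGES}}

    # ---- simulate -------------------------------------------------------
    stage = "simulate"
    sim_cfg = cfg.sim_config()
    cohort = simulate_cohort(sim_cfg)
    input_dir = out / "inputs"
    paths = write_cohort(cohort, input_dir)
    manifest["stages"][stage] = {
        "status": "complete",
        "n_samples": cohort.genotypes.n_samples,
        "n_genes": len(cohort.expression.gene_ids),
        "n_variants": cohort.genotypes.n_variants,
        "checksums": {k: _sha256(v) for k, v in sorted(paths.items())},
    }

    # ---- qc-genotypes ---------------------------------------------------
    stage = "qc_genotypes"
    geno = preprocess.filter_genotypes(
        cohort.genotypes,
        maf_min=cfg.maf_min,
        snp_missing_max=cfg.snp_missing_max,
        sample_missing_max=cfg.sample_missing_max,
        r2_min=cfg.r2_min,
    )
    gpcs = preprocess.genotype_pcs(geno, k=cfg.n_genotype_pcs)
    _io.write_matrix_tsv(gpcs, out / "genotype_pcs.tsv", index_label="sample_id")
    manifest["stages"][stage] = {
        "status": "complete",
        "n_variants_kept": geno.n_variants,
        "n_variants_removed": cohort.genotypes.n_variants - geno.n_variants,
        "n_samples_kept": geno.n_samples,
    }

    # ---- qc-expression --------------------------------------------------
    stage = "qc_expression"
    expr = cohort.expression.subset_samples(geno.samples)
    n_before = len(expr.gene_ids)
    expr = preprocess.filter_genes(expr, cfg.tpm_min, cfg.count_min, cfg.frac_min)
    preprocess.normalize_expression(expr)
    outliers = preprocess.expression_outliers(expr, cfg.outlier_pcs, cfg.outlier_sd)
    if outliers:
        kept = [s for s in expr.samples if s not in set(outliers)]
        expr = expr.subset_samples(kept)
        keep_idx = [geno.samples.index(s) for s in kept]
        geno = geno.subset(sample_idx=np.asarray(keep_idx))
        preprocess.normalize_expression(expr)
    hf = preprocess.hidden_factors(expr, k=min(cfg.n_hidden_factors, len(expr.samples) - 1))
    preprocess.transform_expression(expr)
    covars = preprocess.build_covariates(
        gpcs.loc[expr.samples], hf, cohort.sex
    )
    _io.write_matrix_tsv(covars, out / "covariates.tsv", index_label="sample_id")
    som = cohort.somatic.subset_samples(expr.samples)
    som = SomaticTable(som.cna.loc[expr.gene_ids], som.mutation.loc[expr.gene_ids])
    manifest["stages"][stage] = {
        "status": "complete",
        "n_genes_kept": len(expr.gene_ids),
        "n_genes_removed": n_before - len(expr.gene_ids),
        "n_outlier_samples": len(outliers),
        "outliers": outliers,
    }

    # ---- map-cis --------------------------------------------------------
    stage = "map_cis"
    cis_res = map_cis(
        geno, expr, som, covars,
        window=cfg.window, mac_min=cfg.mac_min,
        n_perm_min=cfg.n_perm_min, n_perm_max=cfg.n_perm_max,
        seed=stage_seed(cfg.seed, stage), fdr=cfg.egene_fdr,
    )
    _io.write_table_tsv(cis_res, out / "cis_results.tsv")
    som_res = somqtl_test(expr.transformed, som, covars, fdr=cfg.egene_fdr)
    _io.write_table_tsv(som_res, out / "somqtl_results.tsv")
    egenes = set(cis_res.loc[cis_res["is_egene"], "gene_id"]) if not cis_res.empty else set()
    manifest["stages"][stage] = {
        "status": "complete",
        "n_genes_tested": int(len(cis_res)),
        "n_egenes": len(egenes),
        "n_somqtl_tested": int(len(som_res)),
        "n_somqtl_significant": int(som_res["significant"].sum()) if not som_res.empty else 0,
    }

    # ---- map-interaction ------------------------------------------------
    stage = "map_interaction"
    int_res = map_interaction(
        geno, expr, som, covars, cohort.purity,
        window=cfg.window, mac_min=cfg.mac_min,
        n_perm_min=cfg.n_perm_min, n_perm_max=cfg.n_perm_max,
        seed=stage_seed(cfg.seed, stage), fdr=cfg.iegene_fdr,
        alpha=cfg.tertile_alpha,
    )
    _io.write_table_tsv(int_res, out / "interaction_results.tsv")
    n_iegenes = int(int_res["is_iegene"].sum()) if not int_res.empty else 0
    manifest["stages"][stage] = {
        "status": "complete",
        "n_genes_tested": int(len(int_res)),
        "n_iegenes": n_iegenes,
    }

    # ---- summarize ------------------------------------------------------
    stage = "summarize"
    expressed = set(expr.gene_ids)
    frac = stats.egene_fraction(egenes & expressed, expressed) if expressed else np.nan
    n_som_sig = int(som_res["significant"].sum()) if not som_res.empty else 0
    ratio = stats.qtl_ratio(len(egenes), n_som_sig) if n_som_sig else np.nan
    math = stats.math_scores_by_sample(cohort.mutations, cohort.purity)
    math = math.reindex(expr.samples)
    _io.write_series_tsv(math, out / "math_scores.tsv", "sample_id")

    # per-gene variance partitioning over the model's predictor groups
    lead = {} if cis_res.empty else dict(zip(cis_res["gene_id"], cis_res["lead_variant"]))
    var_id_to_idx = {v: i for i, v in enumerate(geno.variants["id"])}
    hf_cols = [c for c in covars.columns if c.startswith("HF")]
    pc_cols = [c for c in covars.columns if c.startswith("PC")]
    vf_rows = []
    for gene_id in expr.gene_ids:
        design = {
            "hidden_factors": covars[hf_cols].to_numpy(),
            "genotype_pcs": covars[pc_cols].to_numpy(),
        }
        if "sex" in covars.columns:
            design["sex"] = covars["sex"].to_numpy()
        cna, mut = som.gene_row(gene_id, expr.samples)
        design["cna"] = cna
        design["mutation"] = mut
        if gene_id in lead:
            design["genotype"] = geno.dosages[:, var_id_to_idx[lead[gene_id]]]
        try:
            fr = stats.variance_fractions(
                expr.transformed.loc[gene_id].to_numpy(), design
            )
        except ValueError:
            continue
        fr["gene_id"] = gene_id
        vf_rows.append(fr)
    vf = pd.DataFrame(vf_rows)
    if not vf.empty:
        cols = ["gene_id"] + [c for c in vf.columns if c != "gene_id"]
        vf = vf[cols].fillna(0.0)
    _io.write_table_tsv(vf, out / "variance_fractions.tsv")

    summary = pd.DataFrame(
        [
            ("n_expressed_genes", float(len(expressed))),
            ("n_egenes", float(len(egenes))),
            ("egene_fraction", float(frac)),
            ("n_somqtl_significant", float(n_som_sig)),
            ("eqtl_somqtl_ratio", float(ratio)),
            ("n_iegenes", float(n_iegenes)),
            ("median_math", float(np.nanmedian(math.to_numpy()))),
        ],
        columns=["metric", "value"],
    )
    _io.write_table_tsv(summary, out / "summary.tsv")
    manifest["stages"][stage] = {"status": "complete"}

    manifest["config"] = dataclasses.asdict(cfg)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
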