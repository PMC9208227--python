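"""Genotype QC and expression normalization / covariate estimation.

Genotype side: MAF, missingness and imputation-quality filters, then
ancestry principal components on the standardized dosage matrix.
Expression side: median-of-ratios size factors, joint TPM/count gene
filtering, PCA-based sample-outlier flagging, hidden expression factors
(PCA standing in for Bayesian factor models such as PEER), and the
rank-based inverse normal transform used throughout eQTL practice.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .datatypes import ExpressionSet, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_genotypes",
    "genotype_pcs",
    "size_factors",
    "normalize_expression",
    "filter_genes",
    "expression_outliers",
    "hidden_factors",
    "inverse_normal",
    "transform_expression",
    "build_covariates",
]


def filter_genotypes(
    g: GenotypeMatrix,
    maf_min: float = 0.01,
    snp_missing_max: float = 0.95,
    sample_missing_max: float = 0.025,
    r2_min: float = 0.3,
    quality_mask: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Apply variant and sample QC filters; mean-impute residual missingness.

    Variants are dropped for MAF < ``maf_min``, missingness >
    ``snp_missing_max`` or (when an ``r2`` column is present) imputation
    r-squared < ``r2_min``; samples are dropped for missingness >
    ``sample_missing_max``. ``quality_mask`` optionally marks individual
    calls (samples x variants, True = unreliable) to be set missing first,
    the generic stand-in for an array-level per-call quality score.
    """
    for name, v in (("maf_min", maf_min), ("snp_missing_max", snp_missing_max),
                    ("sample_missing_max", sample_missing_max)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    d = g.dosages.copy()
    if quality_mask is not None:
        quality_mask = np.asarray(quality_mask, dtype=bool)
        if quality_mask.shape != d.shape:
            raise ValueError("quality_mask shape mismatch")
        d[quality_mask] = np.nan

    work = GenotypeMatrix(d, g.variants, g.samples)
    keep_var = work.maf() >= maf_min
    n_maf = int((~keep_var).sum())
    miss_var = work.variant_missing_rate() > snp_missing_max
    keep_var &= ~miss_var
    n_r2 = 0
    if "r2" in g.variants.columns:
        r2 = g.variants["r2"].to_numpy(dtype=float)
        low = np.where(np.isnan(r2), False, r2 < r2_min)
        n_r2 = int((low & keep_var).sum())
        keep_var &= ~low
    keep_sample = work.sample_missing_rate() <= sample_missing_max
    logger.info(
        "genotype QC: removed %d variants (MAF), %d (missingness), %d (r2), %d samples",
        n_maf, int(miss_var.sum()), n_r2, int((~keep_sample).sum()),
    )
    if not keep_var.any() or not keep_sample.any():
        raise ValueError("genotype QC removed all variants or all samples")

    out = work.subset(np.flatnonzero(keep_sample), np.flatnonzero(keep_var))
    # mean-impute whatever missingness is left, per variant
    col_mean = np.nanmean(out.dosages, axis=0)
    idx = np.where(np.isnan(out.dosages))
    out.dosages[idx] = col_mean[idx[1]]
    return out


def _signed_pcs(X: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k PC scores of a centered matrix with a fixed sign convention:
    each component's largest-magnitude loading is made positive."""
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(k, S.size)
    scores = U[:, :k] * S[:k]
    load = Vt[:k]
    for j in range(k):
        i = int(np.argmax(np.abs(load[j])))
        if load[j, i] < 0:
            scores[:, j] = -scores[:, j]
            load[j] = -load[j]
    return scores, load


def genotype_pcs(g: GenotypeMatrix, k: int = 5) -> pd.DataFrame:
    """Ancestry PCs: PCA of the centered, per-variant standardized dosages."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(g.n_samples, g.n_variants):
        raise ValueError("k must be < min(n_samples, n_variants)")
    X = g.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    X -= X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]
    scores, _ = _signed_pcs(X, k)
    return pd.DataFrame(scores, index=g.samples,
                        columns=[f"PC{i + 1}" for i in range(scores.shape[1])])


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the DESeq geometric-mean estimator).

    Uses genes with strictly positive counts in every sample; each
    sample's factor is the median across those genes of count divided by
    the gene's geometric mean.
    """
    mat = counts.to_numpy(dtype=float)
    allpos = (mat > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has strictly positive counts in all samples; "
            "a pseudo-reference fallback is not implemented"
        )
    logmat = np.log(mat[allpos])
    log_geomean = logmat.mean(axis=1)
    factors = np.exp(np.median(logmat - log_geomean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_expression(e: ExpressionSet) -> ExpressionSet:
    """Fill ``normalized`` with counts divided by per-sample size factors."""
    sf = size_factors(e.counts)
    e.normalized = e.counts / sf
    return e


def filter_genes(
    e: ExpressionSet,
    tpm_min: float = 0.1,
    count_min: int = 6,
    frac_min: float = 0.20,
) -> ExpressionSet:
    """Keep genes jointly reaching ``tpm_min`` TPM and ``count_min`` reads
    in at least ``frac_min`` of samples (all thresholds inclusive)."""
    if min(tpm_min, count_min, frac_min) < 0:
        raise ValueError("thresholds must be non-negative")
    ok = (e.tpm.to_numpy() >= tpm_min) & (e.counts.to_numpy() >= count_min)
    frac = ok.mean(axis=1)
    keep = frac >= frac_min
    logger.info("gene filter: kept %d / %d genes", int(keep.sum()), len(keep))
    return e.subset_genes(np.asarray(e.gene_ids)[keep])


def expression_outliers(e: ExpressionSet, n_pcs: int = 6, sd_cut: float = 3.0) -> list[str]:
    """Samples whose log-expression PCA score is more than ``sd_cut``
    standard deviations from the mean on any of the first ``n_pcs`` PCs."""
    if e.normalized is None:
        raise ValueError("run normalize_expression first")
    n = len(e.samples)
    if n_pcs > n - 1:
        raise ValueError("n_pcs must be <= n_samples - 1")
    X = np.log2(e.normalized.to_numpy().T + 1.0)  # samples x genes
    X = X - X.mean(axis=0)
    scores, _ = _signed_pcs(X, n_pcs)
    mean = scores.mean(axis=0)
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    flag = (np.abs(scores - mean) > sd_cut * sd).any(axis=1)
    return [s for s, f in zip(e.samples, flag) if f]


def hidden_factors(e: ExpressionSet, k: int = 15) -> pd.DataFrame:
    """Hidden expression covariates: top-k PCs of the standardized
    log-expression matrix (the PCA stand-in for PEER factors)."""
    if k <= 0:
        raise ValueError("k must be positive")
    if e.normalized is None:
        raise ValueError("run normalize_expression first")
    n = len(e.samples)
    if k >= n:
        raise ValueError("k must be < n_samples")
    X = np.log2(e.normalized.to_numpy() + 1.0)  # genes x samples
    sd = X.std(axis=1)
    keep = sd > 0
    X = (X[keep] - X[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    scores, _ = _signed_pcs(X.T - X.T.mean(axis=0), k)
    return pd.DataFrame(scores, index=e.samples,
                        columns=[f"HF{i + 1}" for i in range(scores.shape[1])])


def inverse_normal(x, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offset.

    Maps ranks to ``Phi^{-1}((rank - c) / (n - 2c + 1))``; ties take the
    average rank. Fails on a constant vector, whose ranks are degenerate.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if np.ptp(x) == 0:
        raise ValueError("inverse_normal undefined for a constant vector")
    ranks = stats.rankdata(x, method="average")
    return ndtri((ranks - c) / (x.size - 2.0 * c + 1.0))


def transform_expression(e: ExpressionSet) -> ExpressionSet:
    """Fill ``transformed`` with the per-gene inverse normal transform of
    the normalized expression (rank-based, so the log scale is immaterial)."""
    if e.normalized is None:
        normalize_expression(e)
    mat = e.normalized.to_numpy()
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        out[i] = inverse_normal(mat[i])
    e.transformed = pd.DataFrame(out, index=e.normalized.index, columns=e.normalized.columns)
    return e


def build_covariates(
    geno_pcs: pd.DataFrame,
    hidden: pd.DataFrame,
    sex: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the covariate table: genotype PCs + hidden factors + sex."""
    parts = [geno_pcs, hidden.reindex(geno_pcs.index)]
    if sex is not None:
        parts.append(sex.reindex(geno_pcs.index).rename("sex").to_frame())
    covars = pd.concat(parts, axis=1)
    if covars.isna().any().any():
        raise ValueError("covariate table has missing values after alignment")
    return covars
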