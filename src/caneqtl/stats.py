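"""Cohort-level summaries: variance partitioning, heterogeneity, sharing.

Variance partitioning uses a fixed-effect semi-partial R^2 decomposition:
the full linear model is fit once, each predictor group is then dropped in
turn, and the group's share is the resulting increase in residual sum of
squares over the total sum of squares (floored at zero, renormalized to
sum to one). For mutually orthogonal groups this equals the marginal R^2
decomposition exactly.

Intratumor heterogeneity is summarized per patient by a cancer cell
fraction (CCF) based MATH score: the median absolute deviation of CCFs
divided by their median. CCF converts a mutation's variant allele
fraction to the fraction of tumor cells carrying it, given tumor purity
and local copy number:

    CCF = VAF * (purity * CN_t + (1 - purity) * CN_n) / (purity * m)

eGene sharing across cohorts is summarized by Jaccard similarity
(optionally min-max scaled across off-diagonal pairs) and per-gene
cohort-count histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "variance_fractions",
    "ccf",
    "math_score",
    "egene_fraction",
    "similarity_matrix",
    "SimilarityMatrix",
    "downsample",
    "qtl_ratio",
    "sharing_counts",
    "SharingSummary",
    "math_scores_by_sample",
]


def variance_fractions(
    expr_gene: np.ndarray,
    design: dict[str, np.ndarray],
) -> dict[str, float]:
    """Decompose a gene's expression variance over predictor groups.

    ``design`` maps group name -> (n,) or (n, k) predictor array. Groups
    must be disjoint predictor sets; constant predictors are dropped with
    a log note. Returns ``{group: fraction, ..., "residual": fraction}``
    summing to 1.
    """
    y = np.asarray(expr_gene, dtype=float)
    n = y.size
    blocks: dict[str, np.ndarray] = {}
    for name, arr in design.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        keep = [j for j in range(arr.shape[1]) if np.ptp(arr[:, j]) > 0]
        if len(keep) < arr.shape[1]:
            logger.info("variance_fractions: dropping constant columns in group %r", name)
        if keep:
            blocks[name] = arr[:, keep]
    names = list(blocks)
    X_full = np.column_stack([np.ones(n)] + [blocks[g] for g in names])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise ValueError("rank-deficient design in variance_fractions")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    yc = y - y.mean()
    tss = float(yc @ yc)
    if tss == 0:
        raise ValueError("constant expression vector")
    rss_full = rss(X_full)
    fractions: dict[str, float] = {}
    for g in names:
        X_wo = np.column_stack([np.ones(n)] + [blocks[h] for h in names if h != g])
        fractions[g] = max(rss(X_wo) - rss_full, 0.0) / tss
    for name in design:
        fractions.setdefault(name, 0.0)
    fractions["residual"] = rss_full / tss
    total = sum(fractions.values())
    return {k: v / total for k, v in fractions.items()}


def ccf(
    vaf,
    purity,
    cn_tumor=2.0,
    cn_normal=2.0,
    multiplicity=1,
) -> np.ndarray | float:
    """Cancer cell fraction of a mutation from its VAF, tumor purity and
    local copy number; clamped to [0, 1.5] (values above 1 are retained up
    to the clamp as super-clonal artifacts). NaN where purity is 0."""
    vaf = np.asarray(vaf, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn_tumor = np.asarray(cn_tumor, dtype=float)
    cn_normal = np.asarray(cn_normal, dtype=float)
    multiplicity = np.asarray(multiplicity, dtype=float)
    if np.any((vaf < 0) | (vaf > 1)):
        raise ValueError("VAF must lie in [0, 1]")
    if np.any(multiplicity < 1):
        raise ValueError("multiplicity must be >= 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = vaf * (purity * cn_tumor + (1.0 - purity) * cn_normal) / (purity * multiplicity)
    out = np.where(purity <= 0, np.nan, out)
    if np.any(~np.isfinite(out) & (purity > 0)):
        logger.warning("non-finite CCF values flagged as NaN")
    n_super = int(np.sum(out > 1.0))
    if n_super:
        logger.info("%d super-clonal CCF values (> 1) clamped at 1.5", n_super)
    out = np.clip(out, 0.0, 1.5)
    return float(out) if out.ndim == 0 else out


def math_score(ccfs, scaled: bool = False) -> float:
    """MATH heterogeneity score of a patient's CCF distribution.

    Default is the plain ratio MAD(CCF) / median(CCF) (no 1.4826
    consistency constant, no x100). ``scaled=True`` gives the original
    MATH convention ``100 * 1.4826 * MAD / median``. Undefined (NaN) for
    fewer than 3 mutations or a non-positive median.
    """
    x = np.asarray(ccfs, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        logger.info("math_score undefined: fewer than 3 mutations")
        return float("nan")
    med = float(np.median(x))
    if med <= 0:
        logger.info("math_score undefined: non-positive median CCF")
        return float("nan")
    mad = float(np.median(np.abs(x - med)))
    ratio = mad / med
    return 100.0 * 1.4826 * ratio if scaled else ratio


def math_scores_by_sample(
    mutations: pd.DataFrame,
    purity: pd.Series,
    scaled: bool = False,
) -> pd.Series:
    """Per-sample MATH score from a mutation table (sample_id, vaf,
    cn_tumor[, cn_normal, multiplicity]) and per-sample purity."""
    out = {}
    for sid, grp in mutations.groupby("sample_id"):
        p = purity.get(sid, np.nan)
        if not np.isfinite(p):
            out[sid] = np.nan
            continue
        c = ccf(
            grp["vaf"].to_numpy(),
            p,
            grp.get("cn_tumor", pd.Series(2.0, index=grp.index)).to_numpy(),
            grp.get("cn_normal", pd.Series(2.0, index=grp.index)).to_numpy(),
            grp.get("multiplicity", pd.Series(1, index=grp.index)).to_numpy(),
        )
        out[sid] = math_score(c, scaled=scaled)
    return pd.Series(out, name="math_score")


def egene_fraction(egenes: set, expressed: set) -> float:
    """Fraction of expressed genes that are eGenes."""
    if not expressed:
        raise ValueError("expressed gene set is empty")
    if not egenes <= expressed:
        raise ValueError("egenes must be a subset of expressed genes")
    return len(egenes) / len(expressed)


@dataclass
class SimilarityMatrix:
    """Pairwise Jaccard similarity between cohort eGene sets.

    ``raw`` holds J(A, B) = |A & B| / |A | B| (diagonal 1); ``scaled``
    min-max rescales the off-diagonal values to [0, 1], where 1 marks the
    most similar pair of distinct cohorts.
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame


def similarity_matrix(egene_sets: dict[str, set]) -> SimilarityMatrix:
    cohorts = list(egene_sets)
    if len(cohorts) < 2:
        raise ValueError("need at least 2 cohorts")
    k = len(cohorts)
    raw = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            a, b = egene_sets[cohorts[i]], egene_sets[cohorts[j]]
            union = len(a | b)
            if union == 0:
                logger.warning("empty union for %s vs %s; J set to 0",
                               cohorts[i], cohorts[j])
                jac = 0.0
            else:
                jac = len(a & b) / union
            raw[i, j] = raw[j, i] = jac
    off = raw[~np.eye(k, dtype=bool)]
    lo, hi = off.min(), off.max()
    scaled = raw.copy()
    mask = ~np.eye(k, dtype=bool)
    if hi > lo:
        scaled[mask] = (raw[mask] - lo) / (hi - lo)
    else:
        logger.info("all off-diagonal similarities equal; scaled values set to 0")
        scaled[mask] = 0.0
    idx = pd.Index(cohorts)
    return SimilarityMatrix(
        raw=pd.DataFrame(raw, index=idx, columns=idx),
        scaled=pd.DataFrame(scaled, index=idx, columns=idx),
    )


def downsample(sample_ids, n: int, seed: int = 0) -> list[str] | None:
    """Seeded uniform sample of ``n`` ids without replacement, sorted.

    Input order does not matter (ids are sorted before drawing). Cohorts
    smaller than ``n`` are skipped (returns None with a log note).
    """
    ids = sorted(sample_ids)
    if n > len(ids):
        logger.info("cohort of %d smaller than n=%d; skipped", len(ids), n)
        return None
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(ids), size=n, replace=False)
    return sorted(ids[i] for i in chosen)


def qtl_ratio(n_egene_assoc: int, n_somqtl: int) -> float:
    """Ratio of germline eQTL associations to somatic QTL associations."""
    if n_somqtl == 0:
        logger.warning("qtl_ratio undefined: zero somQTL associations")
        return float("nan")
    return n_egene_assoc / n_somqtl


@dataclass
class SharingSummary:
    counts: pd.Series  # gene -> number of cohorts in which it is an eGene
    shared_in_all: set
    unique_to_one: set


def sharing_counts(egene_sets: dict[str, set]) -> SharingSummary:
    """How many cohorts call each gene an eGene, plus the fully shared and
    cohort-unique subsets."""
    if not egene_sets:
        raise ValueError("need at least 1 cohort")
    all_genes = set().union(*egene_sets.values())
    counts = pd.Series(
        {g: sum(g in s for s in egene_sets.values()) for g in sorted(all_genes)},
        dtype=int,
    )
    k = len(egene_sets)
    return SharingSummary(
        counts=counts,
        shared_in_all=set(counts.index[counts == k]),
        unique_to_one=set(counts.index[counts == 1]),
    )
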