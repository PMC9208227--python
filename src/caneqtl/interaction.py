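"""Genotype x purity interaction eQTLs and purity-tertile classification.

The interaction model extends the additive eQTL model with a product term:
``expression = genotype + covariates + somatic + purity + genotype*purity``.
Purity is centered before forming the product so that the main and
interaction terms are decorrelated (the product-term coefficient itself
is invariant to the centering). Gene-level calibration permutes the
genotype columns jointly across samples, which preserves the
purity-expression-covariate relationship, and re-uses the Beta
approximation of the cis machinery; ieGenes are called with Storey
q-values at FDR 0.10, reflecting the lower power of the interaction test.

Significant genes are classified by splitting the cohort at purity
tertiles: an effect confined to the high-purity tertile suggests a
tumor-cell-restricted eQTL, one confined to the low-purity tertile a
stroma/immune-restricted eQTL, and significant opposite-sign slopes in
the two tertiles suggest different regulation inside and outside the
tumor compartment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cis import (
    _design,
    beta_adjusted_p,
    cis_window,
    fit_beta,
    mac_filter,
    storey_qvalues,
)
from .datatypes import ExpressionSet, GenotypeMatrix, SomaticTable

logger = logging.getLogger(__name__)

__all__ = [
    "interaction_scan",
    "interaction_gene_pass",
    "InteractionPermResult",
    "call_iegenes",
    "tertile_classify",
    "TertileResult",
    "map_interaction",
]

CLASS_LABELS = (
    "low_purity_only",
    "high_purity_only",
    "opposite_directions",
    "unclassified",
)


def _interaction_basis(
    purity: np.ndarray,
    covars: pd.DataFrame | None,
    som_row: tuple[np.ndarray, np.ndarray] | None,
) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal basis Q of the nuisance design (intercept, covariates,
    somatic state, purity main effect) and the centered purity vector."""
    purity = np.asarray(purity, dtype=float)
    if np.any((purity < 0) | (purity > 1)):
        raise ValueError("purity must lie in [0, 1]")
    if np.ptp(purity) == 0:
        raise ValueError("purity is constant; interaction model undefined")
    pc = purity - purity.mean()
    extra = {"purity": pc}
    if som_row is not None:
        cna, mut = som_row
        if np.ptp(cna) > 0:
            extra["cna_code"] = cna
        if np.ptp(mut) > 0:
            extra["inactivating_mut"] = mut
    X, _ = _design(covars, purity.size, extra)
    Q, _ = np.linalg.qr(X)
    return Q, pc


def _interaction_stats(
    y_r: np.ndarray,
    G: np.ndarray,
    pc: np.ndarray,
    Q: np.ndarray,
    ss_y: float,
    df: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Interaction coefficient and two-sided p per variant.

    Frisch-Waugh-Lovell: project the nuisance design out of ``g`` and
    ``g * pc``, then solve the per-variant 2x2 normal equations for the
    joint (genotype, interaction) block against the projected phenotype.
    """
    GP = G * pc[:, None]
    A = G - Q @ (Q.T @ G)
    B = GP - Q @ (Q.T @ GP)
    s11 = np.einsum("ij,ij->j", A, A)
    s22 = np.einsum("ij,ij->j", B, B)
    s12 = np.einsum("ij,ij->j", A, B)
    c1 = y_r @ A
    c2 = y_r @ B
    det = s11 * s22 - s12 * s12
    tiny = np.finfo(float).tiny
    bad = det <= np.maximum(s11 * s22, tiny) * 1e-12
    det_safe = np.where(bad, 1.0, det)
    b1 = (s22 * c1 - s12 * c2) / det_safe
    b2 = (s11 * c2 - s12 * c1) / det_safe
    rss = np.maximum(ss_y - (b1 * c1 + b2 * c2), 0.0)
    sigma2 = rss / df
    var_b2 = sigma2 * s11 / det_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b2 / np.sqrt(var_b2)
    t = np.where(bad | ~np.isfinite(t), 0.0, t)
    b2 = np.where(bad, 0.0, b2)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return b2, np.maximum(p, np.finfo(float).tiny)


def interaction_scan(
    expr_gene: np.ndarray,
    cis_dosages: np.ndarray,
    purity: np.ndarray,
    covars: pd.DataFrame | None = None,
    som_row: tuple[np.ndarray, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-variant genotype x purity interaction coefficient and p-value."""
    y = np.asarray(expr_gene, dtype=float)
    Q, pc = _interaction_basis(purity, covars, som_row)
    y_r = y - Q @ (Q.T @ y)
    ss_y = float(y_r @ y_r)
    df = y.size - Q.shape[1] - 2
    coef, p = _interaction_stats(y_r, cis_dosages, pc, Q, ss_y, df)
    return pd.DataFrame({"interaction_coef": coef, "interaction_p": p})


@dataclass
class InteractionPermResult:
    lead_local: int
    interaction_coef: float
    nominal_p: float
    empirical_p: float
    beta_shape1: float
    beta_shape2: float
    adjusted_p: float
    n_permutations: int


def interaction_gene_pass(
    expr_gene: np.ndarray,
    cis_dosages: np.ndarray,
    purity: np.ndarray,
    covars: pd.DataFrame | None = None,
    som_row: tuple[np.ndarray, np.ndarray] | None = None,
    n_perm_min: int = 1000,
    n_perm_max: int = 10_000,
    rng: np.random.Generator | int | None = None,
    early_stop_hits: int = 30,
    positions: np.ndarray | None = None,
    chunk: int = 200,
) -> InteractionPermResult:
    """Gene-level interaction pass.

    Takes the minimum interaction p across cis variants and calibrates it
    by permuting genotype rows jointly across samples (expression, purity
    and covariates keep their alignment), with the same adaptive stop and
    Beta-approximation machinery as the cis permutation pass.
    """
    if n_perm_min > n_perm_max:
        raise ValueError("n_perm_min must be <= n_perm_max")
    rng = np.random.default_rng(rng)
    y = np.asarray(expr_gene, dtype=float)
    G = np.asarray(cis_dosages, dtype=float)
    n, n_var = G.shape
    Q, pc = _interaction_basis(purity, covars, som_row)
    y_r = y - Q @ (Q.T @ y)
    ss_y = float(y_r @ y_r)
    df = n - Q.shape[1] - 2
    coef, p = _interaction_stats(y_r, G, pc, Q, ss_y, df)
    if positions is None:
        positions = np.arange(n_var)
    best = p.min()
    cand = np.flatnonzero(p == best)
    lead = int(cand[np.argmin(positions[cand])])
    p_obs = float(best)

    # Permutation loop exploits three identities to stay inside BLAS:
    # y_r is already orthogonal to Q, so the phenotype cross-products need
    # the unprojected permuted genotypes only; the projected Gram entries
    # reduce to raw moments minus ||Q^T P G||^2 terms; and every term of
    # the form (M^T P G) equals (P^T M)^T G, so it is the *small* left
    # factors (Q, Q * pc, the phenotype/purity vectors) that get permuted
    # while G stays fixed for batched matmuls.
    g2 = G * G
    g2sum = g2.sum(axis=0)  # invariant under row permutation
    pc2 = pc * pc
    ypc = y_r * pc
    Qpc = Q * pc[:, None]
    vecs = np.column_stack([y_r, ypc])  # against G
    vecs2 = np.column_stack([pc, pc2])  # against G^2
    k = Q.shape[1]

    def run(n_perm: int) -> np.ndarray:
        out = np.empty(n_perm)
        done = 0
        while done < n_perm:
            b = min(chunk, n_perm - done)
            idx = np.argsort(rng.random((b, n)), axis=1)
            U1 = np.matmul(Q[idx].transpose(0, 2, 1), G)      # (b, k, V)
            U2 = np.matmul(Qpc[idx].transpose(0, 2, 1), G)
            W = np.matmul(vecs[idx].transpose(0, 2, 1), G)    # c1, c2
            W2 = np.matmul(vecs2[idx].transpose(0, 2, 1), g2)  # m1, m2
            s11 = g2sum[None, :] - np.einsum("bkv,bkv->bv", U1, U1)
            s22 = W2[:, 1, :] - np.einsum("bkv,bkv->bv", U2, U2)
            s12 = W2[:, 0, :] - np.einsum("bkv,bkv->bv", U1, U2)
            c1 = W[:, 0, :]
            c2 = W[:, 1, :]
            det = s11 * s22 - s12 * s12
            bad = det <= np.maximum(s11 * s22, np.finfo(float).tiny) * 1e-12
            det_safe = np.where(bad, 1.0, det)
            b1 = (s22 * c1 - s12 * c2) / det_safe
            b2 = (s11 * c2 - s12 * c1) / det_safe
            rss = np.maximum(ss_y - (b1 * c1 + b2 * c2), 0.0)
            var_b2 = rss / df * s11 / det_safe
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.abs(b2) / np.sqrt(var_b2)
            t = np.where(bad | ~np.isfinite(t), 0.0, t)
            out[done:done + b] = 2.0 * stats.t.sf(t.max(axis=1), df)
            done += b
        return out

    minima = run(n_perm_min)
    hits = int(np.sum(minima <= p_obs))
    if hits < early_stop_hits and n_perm_max > n_perm_min:
        minima = np.concatenate([minima, run(n_perm_max - n_perm_min)])
        hits = int(np.sum(minima <= p_obs))
    n_used = minima.size
    empirical_p = (1.0 + hits) / (1.0 + n_used)
    a, b = fit_beta(minima)
    adjusted = float(np.clip(beta_adjusted_p(p_obs, a, b), np.finfo(float).tiny, 1.0))
    return InteractionPermResult(
        lead_local=lead,
        interaction_coef=float(coef[lead]),
        nominal_p=p_obs,
        empirical_p=empirical_p,
        beta_shape1=a,
        beta_shape2=b,
        adjusted_p=adjusted,
        n_permutations=n_used,
    )


def call_iegenes(results: pd.DataFrame, fdr: float = 0.10) -> set[str]:
    """Genes whose interaction q-value is at or below the FDR threshold."""
    if results.empty:
        return set()
    return set(results.loc[results["q_value"] <= fdr, "gene_id"])


@dataclass
class TertileResult:
    class_label: str
    n_low: int
    n_high: int
    slope_low: float
    slope_high: float
    p_low: float
    p_high: float


def _simple_fit(y: np.ndarray, d: np.ndarray) -> tuple[float, float]:
    n = y.size
    dc = d - d.mean()
    ss_d = float(dc @ dc)
    if ss_d == 0 or n < 3:
        return 0.0, 1.0
    yc = y - y.mean()
    slope = float(yc @ dc) / ss_d
    ss_y = float(yc @ yc)
    r2 = 0.0 if ss_y == 0 else (slope * slope * ss_d) / ss_y
    r2 = min(r2, 1.0)
    df = n - 2
    t = np.sqrt(r2 * df / max(1.0 - r2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(t, df)
    return slope, float(p)


def tertile_classify(
    expr_gene: np.ndarray,
    lead_dosage: np.ndarray,
    purity: np.ndarray,
    alpha: float = 0.05,
    min_per_tertile: int = 10,
) -> TertileResult:
    """Classify an interaction eQTL by its behavior in purity tertiles.

    Samples are split at the 1/3 and 2/3 purity quantiles (linear
    interpolation; boundary ties go to the lower tertile). Expression is
    regressed on dosage separately in the low and high tertiles; the label
    records in which tertile(s) the association reaches ``alpha`` and
    whether the two slopes disagree in sign.
    """
    y = np.asarray(expr_gene, dtype=float)
    d = np.asarray(lead_dosage, dtype=float)
    purity = np.asarray(purity, dtype=float)
    q1, q2 = np.quantile(purity, [1.0 / 3.0, 2.0 / 3.0])
    low = purity <= q1
    high = purity > q2
    n_low, n_high = int(low.sum()), int(high.sum())
    if min(n_low, n_high) < min_per_tertile:
        logger.info("tertile too small (%d/%d); leaving unclassified", n_low, n_high)
        return TertileResult("unclassified", n_low, n_high,
                             np.nan, np.nan, np.nan, np.nan)
    slope_low, p_low = _simple_fit(y[low], d[low])
    slope_high, p_high = _simple_fit(y[high], d[high])
    if p_low < alpha and p_high >= alpha:
        label = "low_purity_only"
    elif p_high < alpha and p_low >= alpha:
        label = "high_purity_only"
    elif p_low < alpha and p_high < alpha and slope_low * slope_high < 0:
        label = "opposite_directions"
    else:
        label = "unclassified"
    return TertileResult(label, n_low, n_high, slope_low, slope_high, p_low, p_high)


def map_interaction(
    geno: GenotypeMatrix,
    expr: ExpressionSet,
    som: SomaticTable | None,
    covars: pd.DataFrame | None,
    purity: pd.Series,
    window: int = 1_000_000,
    mac_min: int = 5,
    n_perm_min: int = 1000,
    n_perm_max: int = 10_000,
    seed: int = 0,
    fdr: float = 0.10,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the interaction pass for every gene, call ieGenes, and classify
    the significant ones by purity tertile."""
    if expr.transformed is None:
        raise ValueError("expression must be transformed (run transform_expression)")
    samples = list(expr.transformed.columns)
    if samples != geno.samples:
        raise ValueError("expression and genotype samples misaligned")
    pur = purity.reindex(samples).to_numpy(dtype=float)
    pos_all = geno.variants["pos"].to_numpy()
    ids_all = geno.variants["id"].to_numpy()
    root = np.random.SeedSequence(seed)
    rows = []
    for gene_id, child in zip(expr.transformed.index, root.spawn(len(expr.transformed.index))):
        gene = expr.genes.loc[gene_id]
        idx = cis_window(gene, geno.variants, window)
        if idx.size == 0:
            continue
        D = geno.dosages[:, idx]
        keep = mac_filter(D, mac_min)
        if keep.size == 0:
            continue
        idx = idx[keep]
        D = D[:, keep]
        som_row = som.gene_row(gene_id, samples) if som is not None else None
        y = expr.transformed.loc[gene_id].to_numpy(dtype=float)
        res = interaction_gene_pass(
            y, D, pur, covars, som_row,
            n_perm_min=n_perm_min, n_perm_max=n_perm_max,
            rng=np.random.default_rng(child), positions=pos_all[idx],
        )
        rows.append(
            {
                "gene_id": gene_id,
                "lead_variant": str(ids_all[idx[res.lead_local]]),
                "lead_index": int(idx[res.lead_local]),
                "n_variants_tested": int(idx.size),
                "interaction_coef": res.interaction_coef,
                "interaction_p": res.nominal_p,
                "empirical_p": res.empirical_p,
                "beta_shape1": res.beta_shape1,
                "beta_shape2": res.beta_shape2,
                "adjusted_p": res.adjusted_p,
                "n_permutations": res.n_permutations,
            }
        )
    frame = pd.DataFrame(rows)
    if frame.empty:
        return frame
    frame["q_value"] = storey_qvalues(frame["adjusted_p"].to_numpy())
    frame["is_iegene"] = frame["q_value"] <= fdr

    labels, extras = [], []
    for _, row in frame.iterrows():
        if not row["is_iegene"]:
            labels.append("")
            extras.append((np.nan,) * 4 + (0, 0))
            continue
        y = expr.transformed.loc[row["gene_id"]].to_numpy(dtype=float)
        d = geno.dosages[:, int(row["lead_index"])]
        tert = tertile_classify(y, d, pur, alpha=alpha)
        labels.append(tert.class_label)
        extras.append((tert.slope_low, tert.slope_high, tert.p_low, tert.p_high,
                       tert.n_low, tert.n_high))
    frame["class_label"] = labels
    frame[["slope_low", "slope_high", "p_low", "p_high", "n_low", "n_high"]] = pd.DataFrame(
        extras, index=frame.index
    )
    return frame.drop(columns=["lead_index"])
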