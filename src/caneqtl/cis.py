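"""Two-stage cis-eQTL mapping with permutation-based gene-level inference.

The model is the classic two-part regression used in tumor eQTL work:
expression is first residualized on technical covariates (genotype PCs,
hidden expression factors, sex) plus the gene's somatic state (extreme
copy-number code and inactivating-mutation indicator), the residuals are
re-normalized by the inverse normal transform, and each cis variant is
then tested by simple linear regression. Gene-level significance comes
from an adaptive permutation pass whose null minima are summarized by a
maximum-likelihood Beta fit, and eGenes are called with Storey q-values.

Also here: somatic-alteration QTL tests (somQTLs) sharing the multiple
testing route, and the allelic fold change effect-size summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma

from .datatypes import CisGeneResult, ExpressionSet, GenotypeMatrix, SomaticTable
from .preprocess import inverse_normal

logger = logging.getLogger(__name__)

__all__ = [
    "residualize",
    "cis_window",
    "mac_filter",
    "nominal_scan",
    "fit_beta",
    "beta_adjusted_p",
    "permutation_pass",
    "PermResult",
    "storey_qvalues",
    "call_egenes",
    "somqtl_test",
    "allelic_fold_change",
    "map_cis",
]

AFC_CLAMP = np.log2(100.0)  # +/- 100-fold


# ---------------------------------------------------------------------------
# design helpers

def _design(covars: pd.DataFrame | np.ndarray | None, n: int,
            extra: dict[str, np.ndarray] | None = None) -> tuple[np.ndarray, list[str]]:
    """Intercept + covariates + extra columns, dropping constant columns
    (other than the intercept) with a log note; raises on rank deficiency."""
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    if covars is not None:
        frame = covars if isinstance(covars, pd.DataFrame) else pd.DataFrame(covars)
        for name in frame.columns:
            cols.append(frame[name].to_numpy(dtype=float))
            names.append(str(name))
    for name, col in (extra or {}).items():
        col = np.asarray(col, dtype=float)
        if np.ptp(col) == 0:
            logger.info("dropping constant design column %r", name)
            continue
        cols.append(col)
        names.append(name)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}): "
                         f"columns {names}")
    return X, names


def residualize(
    expr_gene: np.ndarray,
    covars: pd.DataFrame | None,
    som_row: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """OLS residuals of expression on covariates and somatic state,
    re-normalized by the inverse normal transform."""
    y = np.asarray(expr_gene, dtype=float)
    extra = {}
    if som_row is not None:
        cna, mut = som_row
        extra = {"cna_code": cna, "inactivating_mut": mut}
    X, _ = _design(covars, y.size, extra)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    # a (near-)perfect fit leaves rank-degenerate residuals that the INT
    # cannot order meaningfully
    if np.var(resid) <= 1e-12 * max(np.var(y), np.finfo(float).tiny):
        raise ValueError("residual variance is degenerate (expression is "
                         "explained exactly by the covariates)")
    return inverse_normal(resid)


def cis_window(gene: pd.Series, variants: pd.DataFrame, window: int = 1_000_000) -> np.ndarray:
    """Indices of variants within ``window`` bp of the gene body, inclusive."""
    if window < 0:
        raise ValueError("window must be >= 0")
    on_chrom = (variants["chrom"] == gene["chrom"]).to_numpy()
    pos = variants["pos"].to_numpy()
    inside = (pos >= gene["start"] - window) & (pos <= gene["end"] + window)
    return np.flatnonzero(on_chrom & inside)


def mac_filter(dosages: np.ndarray, mac_min: int = 5) -> np.ndarray:
    """Variant indices whose minor allele count (on rounded hard calls)
    reaches ``mac_min``."""
    if mac_min < 0:
        raise ValueError("mac_min must be >= 0")
    hard = np.round(dosages)
    alt = hard.sum(axis=0)
    mac = np.minimum(alt, 2 * dosages.shape[0] - alt)
    return np.flatnonzero(mac >= mac_min)


# ---------------------------------------------------------------------------
# nominal association

def _corr_stats(y: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column simple-regression (slope, t, p) of y on D."""
    n = y.size
    yc = y - y.mean()
    Dc = D - D.mean(axis=0)
    ss_y = float(yc @ yc)
    ss_d = np.einsum("ij,ij->j", Dc, Dc)
    if np.any(ss_d == 0):
        raise ValueError("zero-variance variant in nominal scan (apply mac_filter)")
    cov = yc @ Dc
    r = cov / np.sqrt(ss_y * ss_d)
    r = np.clip(r, -1.0, 1.0)
    slope = cov / ss_d
    df = n - 2
    denom = np.maximum(1.0 - r * r, np.finfo(float).tiny)
    with np.errstate(over="ignore"):
        t = r * np.sqrt(df / denom)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.maximum(p, np.finfo(float).tiny)
    return slope, t, p


def nominal_scan(y: np.ndarray, dosages: np.ndarray) -> pd.DataFrame:
    """Simple linear regression of the residualized phenotype on each cis
    variant's dosage; two-sided t test on n-2 df."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    if dosages.ndim != 2 or dosages.shape[1] == 0:
        raise ValueError("need at least one cis variant")
    slope, t, p = _corr_stats(y, dosages)
    return pd.DataFrame({"slope": slope, "t": t, "p": p})


def lead_index(p: np.ndarray, pos: np.ndarray) -> int:
    """Lead variant: minimum p, ties broken by smaller genomic position."""
    best = p.min()
    cand = np.flatnonzero(p == best)
    return int(cand[np.argmin(pos[cand])])


# ---------------------------------------------------------------------------
# Beta approximation of the permutation null

def _beta_loglik(a: float, b: float, sl: float, sl1: float, n: int) -> float:
    from scipy.special import betaln

    return (a - 1) * sl + (b - 1) * sl1 - n * betaln(a, b)


def fit_beta(pmins: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(shape1, shape2) fit to permutation minima.

    Method-of-moments start, Newton refinement on the two-parameter score
    (digamma/trigamma); falls back to the moment estimates if Newton does
    not converge.
    """
    x = np.clip(np.asarray(pmins, dtype=float), 1e-300, 1.0 - 1e-12)
    n = x.size
    m, v = float(x.mean()), float(x.var())
    if v <= 0:
        return 1.0, 1.0
    common = m * (1.0 - m) / v - 1.0
    a = max(m * common, 1e-3)
    b = max((1.0 - m) * common, 1e-3)
    sl = float(np.sum(np.log(x)))
    sl1 = float(np.sum(np.log1p(-x)))
    theta = np.array([a, b])
    converged = False
    for _ in range(100):
        ga = sl - n * (digamma(theta[0]) - digamma(theta.sum()))
        gb = sl1 - n * (digamma(theta[1]) - digamma(theta.sum()))
        grad = np.array([ga, gb])
        tri_sum = polygamma(1, theta.sum())
        H = -n * np.array(
            [
                [polygamma(1, theta[0]) - tri_sum, -tri_sum],
                [-tri_sum, polygamma(1, theta[1]) - tri_sum],
            ]
        )
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        new = theta - step
        if not np.all(np.isfinite(new)) or np.any(new <= 0):
            new = np.maximum(theta - 0.5 * step, theta / 2.0)
        if np.max(np.abs(new - theta) / np.maximum(theta, 1e-8)) < 1e-10:
            theta = new
            converged = True
            break
        theta = new
    if not converged and not np.all(np.isfinite(theta)):
        logger.warning("Beta MLE failed to converge; using method-of-moments fit")
        return a, b
    if not converged:
        logger.warning("Beta MLE hit iteration limit; keeping last iterate")
    return float(theta[0]), float(theta[1])


def beta_adjusted_p(p_obs: float, shape1: float, shape2: float) -> float:
    """Gene-level adjusted p: Beta CDF of the observed minimum nominal p."""
    return float(stats.beta.cdf(p_obs, shape1, shape2))


@dataclass
class PermResult:
    empirical_p: float
    beta_shape1: float
    beta_shape2: float
    adjusted_p: float
    n_permutations: int
    perm_minima: np.ndarray


def _perm_minima(yc: np.ndarray, Dc: np.ndarray, inv_norms: np.ndarray,
                 ss_y: float, df: int, rng: np.random.Generator,
                 n_perm: int, chunk: int = 500) -> np.ndarray:
    """Minimum nominal p over cis variants for ``n_perm`` phenotype
    permutations, computed from the max |correlation| per permutation."""
    out = np.empty(n_perm)
    done = 0
    inv_sy = 1.0 / np.sqrt(ss_y)
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, yc.size)), axis=1)
        Yp = yc[idx]
        R = (Yp @ Dc) * (inv_norms[None, :] * inv_sy)
        rmax = np.clip(np.max(np.abs(R), axis=1), 0.0, 1.0)
        tmax = rmax * np.sqrt(df / np.maximum(1.0 - rmax * rmax, np.finfo(float).tiny))
        out[done:done + b] = 2.0 * stats.t.sf(tmax, df)
        done += b
    return out


def permutation_pass(
    y: np.ndarray,
    cis_dosages: np.ndarray,
    n_perm_min: int = 1000,
    n_perm_max: int = 10_000,
    rng: np.random.Generator | int | None = None,
    early_stop_hits: int = 30,
) -> PermResult:
    """Adaptive permutation pass with Beta approximation.

    Runs ``n_perm_min`` phenotype permutations recording the minimum
    nominal p across cis variants; stops early if at least
    ``early_stop_hits`` permuted minima undercut the observed minimum,
    otherwise continues to ``n_perm_max``. The empirical p uses the
    ``(1 + hits) / (1 + N)`` estimator; the adjusted p is the CDF of the
    maximum-likelihood Beta fit at the observed minimum.
    """
    if n_perm_min > n_perm_max:
        raise ValueError("n_perm_min must be <= n_perm_max")
    rng = np.random.default_rng(rng)
    y = np.asarray(y, dtype=float)
    n = y.size
    _, _, p = _corr_stats(y, cis_dosages)
    p_obs = float(p.min())

    yc = y - y.mean()
    Dc = cis_dosages - cis_dosages.mean(axis=0)
    ss_d = np.einsum("ij,ij->j", Dc, Dc)
    inv_norms = 1.0 / np.sqrt(ss_d)
    ss_y = float(yc @ yc)
    df = n - 2

    minima = _perm_minima(yc, Dc, inv_norms, ss_y, df, rng, n_perm_min)
    hits = int(np.sum(minima <= p_obs))
    if hits < early_stop_hits and n_perm_max > n_perm_min:
        more = _perm_minima(yc, Dc, inv_norms, ss_y, df, rng, n_perm_max - n_perm_min)
        minima = np.concatenate([minima, more])
        hits = int(np.sum(minima <= p_obs))
    n_used = minima.size
    empirical_p = (1.0 + hits) / (1.0 + n_used)
    a, b = fit_beta(minima)
    adjusted = beta_adjusted_p(p_obs, a, b)
    adjusted = float(np.clip(adjusted, np.finfo(float).tiny, 1.0))
    return PermResult(empirical_p, a, b, adjusted, n_used, minima)


# ---------------------------------------------------------------------------
# Storey q-values

def storey_qvalues(
    p: np.ndarray,
    lambdas: np.ndarray | None = None,
    pi0: float | None = None,
) -> np.ndarray:
    """Storey q-values with smoother-based pi0 estimation.

    pi0(lambda) is evaluated on a 0.05..0.95 grid and extrapolated to
    lambda -> 1 with a cubic smoother, clipped to (0, 1]. For families of
    fewer than 100 tests the smoother is unstable and the fixed
    lambda = 0.5 estimator is used instead. Passing ``pi0`` overrides the
    estimate (pi0 = 1 reproduces Benjamini-Hochberg).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if pi0 is None:
        if m < 100:
            logger.info("storey_qvalues: m=%d < 100, using fixed lambda=0.5 pi0", m)
            pi0 = np.mean(p > 0.5) / 0.5
        else:
            if lambdas is None:
                lambdas = np.arange(0.05, 0.951, 0.05)
            pi0_l = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
            coef = np.polyfit(lambdas, pi0_l, 3)
            pi0 = float(np.polyval(coef, 1.0))
        pi0 = float(np.clip(pi0, 1.0 / m, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.clip(q, 0.0, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_egenes(results: pd.DataFrame, fdr: float = 0.05) -> set[str]:
    """Genes whose q-value is at or below the FDR threshold."""
    if results.empty:
        return set()
    hit = results["q_value"] <= fdr
    return set(results.loc[hit, "gene_id"])


# ---------------------------------------------------------------------------
# somatic QTLs

def somqtl_test(
    expr: pd.DataFrame,
    som: SomaticTable,
    covars: pd.DataFrame | None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene association of expression with somatic state.

    Regresses each gene's transformed expression on covariates plus its
    CNA code and mutation indicator, reporting the t-test p of each
    non-constant somatic coefficient; Storey q across the whole
    gene-predictor family. Genes without somatic events are skipped.
    """
    samples = list(expr.columns)
    rows = []
    for gene_id in expr.index:
        y = expr.loc[gene_id].to_numpy(dtype=float)
        cna, mut = som.gene_row(gene_id, samples)
        extra = {}
        if np.ptp(cna) > 0:
            extra["cna"] = cna
        if np.ptp(mut) > 0:
            extra["mutation"] = mut
        if not extra:
            continue
        X, names = _design(covars, y.size, extra)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        df = y.size - X.shape[1]
        sigma2 = float(resid @ resid) / df
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * np.diag(xtx_inv))
        for predictor in extra:
            j = names.index(predictor)
            t = beta[j] / se[j]
            pval = 2.0 * stats.t.sf(abs(t), df)
            rows.append((gene_id, predictor, float(beta[j]),
                         float(max(pval, np.finfo(float).tiny))))
    out = pd.DataFrame(rows, columns=["gene_id", "predictor", "coefficient", "p"])
    if out.empty:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = storey_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] <= fdr
    return out


# ---------------------------------------------------------------------------
# allelic fold change

def allelic_fold_change(
    expr_linear: np.ndarray,
    dosage: np.ndarray,
    covars: pd.DataFrame | None = None,
) -> float:
    """log2 allelic fold change of a cis variant.

    Covariate effects are removed on the log scale, the adjusted linear
    expression is regressed on dosage, and
    ``aFC = log2((b0 + 2 b1) / b0)``, clamped to +/- log2(100). Returns
    NaN (flagged) when the fitted homozygous-reference mean is
    non-positive.
    """
    e = np.asarray(expr_linear, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if np.any(e < 0):
        raise ValueError("expression must be non-negative")
    if np.ptp(d) == 0:
        raise ValueError("variant is monomorphic")
    if covars is not None:
        z = np.log2(e + 1.0)
        X, _ = _design(covars, e.size)
        beta, *_ = np.linalg.lstsq(X, z, rcond=None)
        z_adj = z - X @ beta + z.mean()
        e = np.maximum(np.exp2(z_adj) - 1.0, 0.0)
    X = np.column_stack([np.ones_like(d), d])
    (b0, b1), *_ = np.linalg.lstsq(X, e, rcond=None)
    if b0 <= 0 or b0 + 2.0 * b1 <= 0:
        logger.warning("aFC undefined: non-positive fitted allele expression")
        return float("nan")
    afc = np.log2((b0 + 2.0 * b1) / b0)
    return float(np.clip(afc, -AFC_CLAMP, AFC_CLAMP))


# ---------------------------------------------------------------------------
# gene-by-gene orchestration

def map_cis(
    geno: GenotypeMatrix,
    expr: ExpressionSet,
    som: SomaticTable | None,
    covars: pd.DataFrame | None,
    window: int = 1_000_000,
    mac_min: int = 5,
    n_perm_min: int = 1000,
    n_perm_max: int = 10_000,
    seed: int = 0,
    fdr: float = 0.05,
    compute_afc: bool = True,
) -> pd.DataFrame:
    """Run the full cis pass for every gene and call eGenes.

    Returns one row per testable gene mirroring the usual permutation-pass
    output: lead variant, nominal and Beta-adjusted p, q-value, slope and
    log2 allelic fold change.
    """
    if expr.transformed is None:
        raise ValueError("expression must be transformed (run transform_expression)")
    samples = list(expr.transformed.columns)
    if samples != geno.samples:
        raise ValueError("expression and genotype samples misaligned")
    pos_all = geno.variants["pos"].to_numpy()
    ids_all = geno.variants["id"].to_numpy()
    root = np.random.SeedSequence(seed)
    results: list[CisGeneResult] = []
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
        y = residualize(expr.transformed.loc[gene_id].to_numpy(), covars, som_row)
        scan = nominal_scan(y, D)
        lead_local = lead_index(scan["p"].to_numpy(), pos_all[idx])
        perm = permutation_pass(
            y, D, n_perm_min, n_perm_max, rng=np.random.default_rng(child)
        )
        afc = np.nan
        if compute_afc and expr.normalized is not None:
            try:
                afc = allelic_fold_change(
                    expr.normalized.loc[gene_id].to_numpy(),
                    geno.dosages[:, idx[lead_local]],
                    covars,
                )
            except ValueError:
                afc = np.nan
        tss = gene["start"] if gene["strand"] == "+" else gene["end"]
        results.append(
            CisGeneResult(
                gene_id=gene_id,
                lead_variant=str(ids_all[idx[lead_local]]),
                n_variants_tested=int(idx.size),
                nominal_p_lead=float(scan["p"].iloc[lead_local]),
                slope_lead=float(scan["slope"].iloc[lead_local]),
                beta_shape1=perm.beta_shape1,
                beta_shape2=perm.beta_shape2,
                n_permutations=perm.n_permutations,
                empirical_p=perm.empirical_p,
                adjusted_p=perm.adjusted_p,
                afc_log2=afc,
                distance=int(pos_all[idx[lead_local]] - tss),
            )
        )
    frame = pd.DataFrame([vars(r) for r in results])
    if frame.empty:
        return frame
    frame["q_value"] = storey_qvalues(frame["adjusted_p"].to_numpy())
    frame["is_egene"] = frame["q_value"] <= fdr
    return frame
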