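"""Synthetic tumor cohort generator with a ground-truth registry.

The generator emulates the statistical structure a bulk tumor eQTL analysis
assumes: biallelic germline dosages with a configurable MAF spectrum,
sparse high-level copy-number events and inactivating mutations, bounded
tumor purity, hidden expression confounders, negative-binomial counts with
log-normal library sizes, and cis effects that are shared, tumor-restricted
(scale with purity) or stroma-restricted (scale with 1 - purity).
Every injected effect is recorded in a :class:`TruthTable` so recovery can
be measured downstream.

Genome layout is a single synthetic chromosome with genes tiled at fixed
spacing and variant positions uniform, which is all the cis-mapping
machinery needs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionSet, GenotypeMatrix, SomaticTable

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthTable",
    "CohortData",
    "simulate_genotypes",
    "simulate_cohort",
    "write_cohort",
]

_EFFECT_CLASSES = ("shared", "tumor_restricted", "stroma_restricted")


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    The defaults describe a mid-sized tumor cohort: 200 patients, 200
    expressed genes on one synthetic chromosome, 5,000 common variants,
    a fifth of genes carrying a true cis signal that explains 10% of
    latent expression variance, and somatic event rates in the few-percent
    range typical of high-level alterations.
    """

    n_samples: int = 200
    n_genes: int = 200
    n_variants: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    cis_effect_frac: float = 0.2
    effect_r2: float = 0.1
    effect_class_probs: dict[str, float] = field(
        default_factory=lambda: {
            "shared": 0.6,
            "tumor_restricted": 0.2,
            "stroma_restricted": 0.2,
        }
    )
    somatic_amp_rate: float = 0.02
    somatic_del_rate: float = 0.02
    somatic_mut_rate: float = 0.03
    somatic_effect_size: float = 1.0
    n_hidden_factors: int = 5
    purity_params: tuple[float, float] = (5.0, 2.0)
    purity_bounds: tuple[float, float] = (0.1, 0.99)
    subclone_ccf_means: tuple[float, ...] = (1.0, 0.5, 0.25)
    seed: int = 0
    # layout / noise knobs
    gene_length: int = 10_000
    gene_spacing: int = 500_000
    cis_window: int = 1_000_000
    min_cis_variants: int = 50
    dosage_noise: float = 0.05
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.3
    sigma_hidden: float = 0.6
    sigma_resid: float = 0.6
    base_log_mean_range: tuple[float, float] = (np.log(50.0), np.log(2000.0))
    mutations_per_sample: float = 40.0
    ccf_sd: float = 0.04
    vaf_depth: int | None = 200

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_genes, self.n_variants) <= 0:
            raise ValueError("n_samples, n_genes, n_variants must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.cis_effect_frac <= 1):
            raise ValueError("cis_effect_frac must be in [0, 1]")
        if self.effect_r2 >= 1 or self.effect_r2 < 0:
            raise ValueError("effect_r2 must be in [0, 1)")
        probs = self.effect_class_probs
        if set(probs) - set(_EFFECT_CLASSES):
            raise ValueError(f"effect classes must be among {_EFFECT_CLASSES}")
        total = sum(probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("effect_class_probs must sum to 1")
        if any(p < 0 for p in probs.values()):
            raise ValueError("effect_class_probs must be non-negative")
        for name in ("somatic_amp_rate", "somatic_del_rate", "somatic_mut_rate"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_hidden_factors < 0:
            raise ValueError("n_hidden_factors must be >= 0")
        plo, phi = self.purity_bounds
        if not (0 < plo <= phi <= 1):
            raise ValueError("purity_bounds must lie within (0, 1]")
        if any(c <= 0 or c > 1.0 for c in self.subclone_ccf_means):
            raise ValueError("subclone_ccf_means must lie in (0, 1]")

    def class_prob_vector(self) -> np.ndarray:
        return np.array([self.effect_class_probs.get(c, 0.0) for c in _EFFECT_CLASSES])


@dataclass
class TruthTable:
    """Ground-truth registry of injected effects.

    ``effects`` has one row per true cis effect (gene_id, variant_id,
    effect_class, slope); ``variance`` has one row per gene with the
    realized latent variance fractions (genotype, somatic, hidden,
    residual), which sum to at most 1.
    """

    effects: pd.DataFrame
    variance: pd.DataFrame

    def effect_genes(self) -> set[str]:
        return set(self.effects["gene_id"])

    def class_of(self, gene_id: str) -> str | None:
        hit = self.effects.loc[self.effects["gene_id"] == gene_id, "effect_class"]
        return None if hit.empty else str(hit.iloc[0])


@dataclass
class CohortData:
    """Bundle returned by :func:`simulate_cohort`."""

    genotypes: GenotypeMatrix
    expression: ExpressionSet
    somatic: SomaticTable
    purity: pd.Series
    sex: pd.Series
    mutations: pd.DataFrame
    truth: TruthTable


def _gene_annotation(cfg: SimConfig) -> pd.DataFrame:
    starts = cfg.cis_window + np.arange(cfg.n_genes) * cfg.gene_spacing + 1
    genes = pd.DataFrame(
        {
            "id": [f"gene{g:04d}" for g in range(cfg.n_genes)],
            "chrom": "chrS",
            "start": starts,
            "end": starts + cfg.gene_length - 1,
            "strand": np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-"),
        }
    ).set_index("id", drop=False)
    genes.index.name = None
    return genes


def _chrom_length(cfg: SimConfig) -> int:
    genes = _gene_annotation(cfg)
    return int(genes["end"].iloc[-1] + cfg.cis_window)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages on a single synthetic chromosome.

    Variant positions are uniform over the chromosome; every gene must end
    up with at least ``cfg.min_cis_variants`` variants inside its cis
    window, otherwise the deficit is reported and the call fails.
    """
    rng = np.random.default_rng([cfg.seed, 0])
    length = _chrom_length(cfg)
    if cfg.n_variants > length:
        raise ValueError("n_variants exceeds chromosome length")
    pos = np.sort(rng.choice(length, size=cfg.n_variants, replace=False)) + 1

    genes = _gene_annotation(cfg)
    deficits = []
    for gid, row in genes.iterrows():
        lo, hi = row["start"] - cfg.cis_window, row["end"] + cfg.cis_window
        n_cis = int(np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left"))
        if n_cis < cfg.min_cis_variants:
            deficits.append((gid, n_cis))
    if deficits:
        worst = ", ".join(f"{g}: {n}" for g, n in deficits[:5])
        raise ValueError(
            f"n_variants={cfg.n_variants} too small to tile all cis windows with "
            f">= {cfg.min_cis_variants} variants; {len(deficits)} deficient windows ({worst} ...)"
        )

    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], cfg.n_variants)
    hard = rng.binomial(2, freq, size=(cfg.n_samples, cfg.n_variants)).astype(float)
    if cfg.dosage_noise > 0:
        noise = rng.uniform(-cfg.dosage_noise, cfg.dosage_noise, hard.shape)
        dosages = np.clip(hard + noise, 0.0, 2.0)
    else:
        dosages = hard

    variants = pd.DataFrame(
        {
            "id": [f"var{i:06d}" for i in range(cfg.n_variants)],
            "chrom": "chrS",
            "pos": pos,
            "ref": "A",
            "alt": "G",
        }
    )
    samples = [f"S{i:04d}" for i in range(cfg.n_samples)]
    return GenotypeMatrix(dosages, variants, samples)


def _truncated_beta(rng, a: float, b: float, lo: float, hi: float, n: int) -> np.ndarray:
    """Inverse-CDF sampling of a Beta(a, b) truncated to [lo, hi]."""
    if lo == hi:
        return np.full(n, lo)
    u = rng.uniform(size=n)
    flo, fhi = stats.beta.cdf([lo, hi], a, b)
    return stats.beta.ppf(flo + u * (fhi - flo), a, b)


def _draw_mutations(
    cfg: SimConfig, rng, samples: list[str], purity: np.ndarray
) -> pd.DataFrame:
    """Per-sample mutation table with CCFs from the configured subclone modes.

    The variant allele fraction follows the standard mixture identity
    ``VAF = CCF * purity * multiplicity / (purity * CN_t + (1 - purity) * CN_n)``,
    optionally with binomial read-sampling noise at ``cfg.vaf_depth``.
    """
    modes = np.asarray(cfg.subclone_ccf_means, dtype=float)
    rows = []
    cn_choices = np.array([1, 2, 3, 4])
    cn_probs = np.array([0.1, 0.7, 0.1, 0.1])
    for s, (sid, pur) in enumerate(zip(samples, purity)):
        n_mut = int(rng.poisson(cfg.mutations_per_sample))
        if n_mut == 0:
            continue
        cluster = rng.integers(0, len(modes), size=n_mut)
        ccf = np.clip(rng.normal(modes[cluster], cfg.ccf_sd), 0.01, 1.0)
        cn_t = rng.choice(cn_choices, size=n_mut, p=cn_probs)
        mult = np.ones(n_mut, dtype=int)
        cn_n = 2.0
        vaf_true = ccf * pur * mult / (pur * cn_t + (1.0 - pur) * cn_n)
        if cfg.vaf_depth is None:
            vaf = vaf_true
        else:
            vaf = rng.binomial(cfg.vaf_depth, vaf_true) / cfg.vaf_depth
        for j in range(n_mut):
            rows.append(
                (sid, f"{sid}_mut{j:03d}", vaf[j], cn_t[j], cn_n, mult[j], ccf[j])
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "mutation_id",
            "vaf",
            "cn_tumor",
            "cn_normal",
            "multiplicity",
            "true_ccf",
        ],
    )


def simulate_cohort(cfg: SimConfig) -> CohortData:
    """Generate a full synthetic cohort plus its ground-truth registry.

    Latent log-expression per gene is
    ``intercept + hidden-factor loadings + somatic shifts + cis term + noise``
    with the cis term ``beta * d`` (shared), ``beta * d * purity``
    (tumor-restricted) or ``beta * d * (1 - purity)`` (stroma-restricted);
    ``beta`` is calibrated so the cis term explains ``cfg.effect_r2`` of
    each effect gene's latent variance. Counts are negative-binomial around
    ``exp(latent)`` with log-normal library-size multipliers.
    """
    geno = simulate_genotypes(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    n, g = cfg.n_samples, cfg.n_genes
    genes = _gene_annotation(cfg)
    samples = geno.samples

    purity = _truncated_beta(
        rng, cfg.purity_params[0], cfg.purity_params[1], *cfg.purity_bounds, n
    )
    if np.ptp(purity) == 0:
        logger.warning("degenerate purity: all samples share purity %.3f", purity[0])
    sex = rng.integers(0, 2, size=n)

    # hidden confounders
    if cfg.n_hidden_factors > 0:
        factors = rng.normal(size=(cfg.n_hidden_factors, n))
        loadings = rng.normal(
            scale=cfg.sigma_hidden / np.sqrt(cfg.n_hidden_factors),
            size=(g, cfg.n_hidden_factors),
        )
        hidden = loadings @ factors
    else:
        hidden = np.zeros((g, n))

    # somatic events
    u = rng.uniform(size=(g, n))
    cna = np.zeros((g, n), dtype=int)
    cna[u < cfg.somatic_amp_rate] = 1
    cna[(u >= cfg.somatic_amp_rate) & (u < cfg.somatic_amp_rate + cfg.somatic_del_rate)] = -1
    mut = (rng.uniform(size=(g, n)) < cfg.somatic_mut_rate).astype(int)
    latent_unit = float(np.hypot(cfg.sigma_hidden, cfg.sigma_resid))
    som_comp = cfg.somatic_effect_size * latent_unit * (cna - mut)

    resid = rng.normal(scale=cfg.sigma_resid, size=(g, n))

    # cis effects
    n_effects = int(round(cfg.cis_effect_frac * g))
    effect_gene_idx = np.sort(rng.choice(g, size=n_effects, replace=False))
    classes = rng.choice(len(_EFFECT_CLASSES), size=n_effects, p=cfg.class_prob_vector())
    pos = geno.variants["pos"].to_numpy()
    hard_maf = np.minimum(
        np.round(geno.dosages).mean(axis=0) / 2.0,
        1.0 - np.round(geno.dosages).mean(axis=0) / 2.0,
    )
    cis_comp = np.zeros((g, n))
    effect_rows = []
    for gi, cls_i in zip(effect_gene_idx, classes):
        row = genes.iloc[gi]
        lo = np.searchsorted(pos, row["start"] - cfg.cis_window, "left")
        hi = np.searchsorted(pos, row["end"] + cfg.cis_window, "right")
        cand = np.arange(lo, hi)
        informative = cand[hard_maf[cand] >= 0.05]
        if informative.size == 0:
            informative = cand
        vi = int(rng.choice(informative))
        cls = _EFFECT_CLASSES[cls_i]
        d = geno.dosages[:, vi]
        if cls == "shared":
            x = d
        elif cls == "tumor_restricted":
            x = d * purity
        else:
            x = d * (1.0 - purity)
        sx = float(np.std(x))
        if sx == 0:
            logger.warning("skipping cis effect for %s: degenerate dosage term", row["id"])
            continue
        rest_var = float(np.var(hidden[gi] + som_comp[gi] + resid[gi]))
        if rest_var == 0:
            rest_var = latent_unit**2
        beta = rng.choice([-1.0, 1.0]) * np.sqrt(
            cfg.effect_r2 / (1.0 - cfg.effect_r2) * rest_var
        ) / sx
        cis_comp[gi] = beta * x
        effect_rows.append((row["id"], geno.variants["id"].iloc[vi], cls, float(beta)))

    base = rng.uniform(*cfg.base_log_mean_range, size=g)
    latent = base[:, None] + hidden + som_comp + cis_comp + resid

    libsize = np.exp(rng.normal(0.0, cfg.libsize_sigma, size=n))
    mu = np.exp(latent) * libsize[None, :]
    if cfg.nb_dispersion > 0:
        lam = rng.gamma(1.0 / cfg.nb_dispersion, cfg.nb_dispersion * mu)
        counts = rng.poisson(lam).astype(np.int64)
    else:
        counts = rng.poisson(mu).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=genes["id"].to_numpy(), columns=samples)
    # genes all share cfg.gene_length, so TPM reduces to per-sample scaling
    rate = counts / cfg.gene_length
    colsum = rate.sum(axis=0)
    colsum[colsum == 0] = 1.0
    tpm_df = pd.DataFrame(rate / colsum * 1e6, index=counts_df.index, columns=samples)

    expr = ExpressionSet(counts=counts_df, tpm=tpm_df, genes=genes)
    somatic = SomaticTable(
        cna=pd.DataFrame(cna, index=counts_df.index, columns=samples),
        mutation=pd.DataFrame(mut, index=counts_df.index, columns=samples),
    )

    # realized latent variance fractions, relative to the component-sum total
    comp = np.stack(
        [
            np.var(cis_comp, axis=1),
            np.var(som_comp, axis=1),
            np.var(hidden, axis=1),
            np.var(resid, axis=1),
        ]
    )
    total = np.var(latent, axis=1)
    total[total == 0] = 1.0
    denom = np.maximum(comp.sum(axis=0), total)
    variance = pd.DataFrame(
        {
            "gene_id": counts_df.index,
            "genotype": comp[0] / denom,
            "somatic": comp[1] / denom,
            "hidden": comp[2] / denom,
            "residual": comp[3] / denom,
        }
    )

    truth = TruthTable(
        effects=pd.DataFrame(
            effect_rows, columns=["gene_id", "variant_id", "effect_class", "slope"]
        ),
        variance=variance,
    )
    mutations = _draw_mutations(cfg, rng, samples, purity)
    return CohortData(
        genotypes=geno,
        expression=expr,
        somatic=somatic,
        purity=pd.Series(purity, index=samples, name="purity"),
        sex=pd.Series(sex, index=samples, name="sex"),
        mutations=mutations,
        truth=truth,
    )


def write_cohort(cohort: CohortData, out_dir: str | Path) -> dict[str, Path]:
    """Write every cohort table as TSV (genes as BED, 0-based half-open)."""
    from . import io as _io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": out / "dosages.tsv",
        "variants": out / "variants.tsv",
        "counts": out / "counts.tsv",
        "tpm": out / "tpm.tsv",
        "genes": out / "genes.bed",
        "somatic_cna": out / "somatic_cna.tsv",
        "somatic_mut": out / "somatic_mutation.tsv",
        "purity": out / "purity.tsv",
        "sex": out / "sex.tsv",
        "mutations": out / "mutations.tsv",
        "truth_effects": out / "truth_effects.tsv",
        "truth_variance": out / "truth_variance.tsv",
    }
    _io.write_dosage_tsv(cohort.genotypes, paths["dosages"], paths["variants"])
    _io.write_matrix_tsv(cohort.expression.counts, paths["counts"])
    _io.write_matrix_tsv(cohort.expression.tpm, paths["tpm"])
    _io.write_gene_bed(cohort.expression.genes, paths["genes"])
    _io.write_matrix_tsv(cohort.somatic.cna, paths["somatic_cna"])
    _io.write_matrix_tsv(cohort.somatic.mutation, paths["somatic_mut"])
    _io.write_series_tsv(cohort.purity, paths["purity"], "sample_id")
    _io.write_series_tsv(cohort.sex, paths["sex"], "sample_id")
    _io.write_table_tsv(cohort.mutations, paths["mutations"])
    _io.write_table_tsv(cohort.truth.effects, paths["truth_effects"])
    _io.write_table_tsv(cohort.truth.variance, paths["truth_variance"])
    return paths
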