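"""Core in-memory containers shared across the pipeline.

All matrices are oriented the way the field's tools expect them:
genotype dosages are samples x variants (as in a transposed VCF),
expression matrices are genes x samples (as count matrices from HTSeq).
Sample and feature identifiers are carried alongside so that subsetting
keeps everything aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "ExpressionSet",
    "SomaticTable",
    "CisGeneResult",
]


@dataclass
class GenotypeMatrix:
    """Imputed dosage matrix with variant metadata.

    Attributes
    ----------
    dosages
        ``(n_samples, n_variants)`` float array of expected alternate-allele
        counts in ``[0, 2]``; missing calls are ``np.nan``.
    variants
        Data frame with columns ``id, chrom, pos, ref, alt`` and optionally
        ``r2`` (imputation quality). ``pos`` is 1-based and strictly
        increasing within a chromosome.
    samples
        Sample identifiers, one per dosage row.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if np.any(bad):
            raise ValueError("dosages outside [0, 2]")
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"variant positions not strictly increasing on {chrom}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Alternate allele frequency per variant, ignoring missing calls."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def variant_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.mean(np.isnan(self.dosages), axis=1)

    def subset(self, sample_idx=None, variant_idx=None) -> "GenotypeMatrix":
        d = self.dosages
        samples = self.samples
        variants = self.variants
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            d = d[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if variant_idx is not None:
            variant_idx = np.asarray(variant_idx)
            d = d[:, variant_idx]
            variants = self.variants.iloc[variant_idx].reset_index(drop=True)
        return GenotypeMatrix(d.copy(), variants, list(samples))


@dataclass
class ExpressionSet:
    """Counts + TPM + gene coordinates, with derived layers filled in by QC.

    ``counts`` and ``tpm`` are genes x samples data frames sharing index and
    columns. ``genes`` carries 1-based inclusive coordinates (``start`` <
    ``end``) plus strand. ``normalized`` (size-factor scaled counts) and
    ``transformed`` (per-gene inverse-normal) are ``None`` until computed.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    genes: pd.DataFrame
    normalized: pd.DataFrame | None = None
    transformed: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.tpm.index):
            raise ValueError("counts and tpm gene index mismatch")
        if list(self.counts.columns) != list(self.tpm.columns):
            raise ValueError("counts and tpm sample columns mismatch")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        g = self.genes
        if not (g["start"] < g["end"]).all():
            raise ValueError("gene coordinates must satisfy start < end")
        missing = set(self.counts.index) - set(g.index)
        if missing:
            raise ValueError(f"{len(missing)} genes lack annotation")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionSet":
        gene_ids = list(gene_ids)
        return ExpressionSet(
            counts=self.counts.loc[gene_ids],
            tpm=self.tpm.loc[gene_ids],
            genes=self.genes.loc[self.genes.index.intersection(gene_ids)].reindex(gene_ids),
            normalized=None if self.normalized is None else self.normalized.loc[gene_ids],
            transformed=None if self.transformed is None else self.transformed.loc[gene_ids],
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionSet":
        samples = list(samples)
        return ExpressionSet(
            counts=self.counts[samples],
            tpm=self.tpm[samples],
            genes=self.genes,
            normalized=None if self.normalized is None else self.normalized[samples],
            transformed=None if self.transformed is None else self.transformed[samples],
        )


@dataclass
class SomaticTable:
    """Per gene x sample somatic state.

    ``cna`` holds the extreme copy-number code: +1 high-level amplification,
    -1 deep deletion, 0 otherwise. ``mutation`` is the inactivating-mutation
    indicator (0/1). Both frames share gene index and sample columns.
    """

    cna: pd.DataFrame
    mutation: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.cna.index.equals(self.mutation.index):
            raise ValueError("cna/mutation gene index mismatch")
        if list(self.cna.columns) != list(self.mutation.columns):
            raise ValueError("cna/mutation sample columns mismatch")
        if not np.isin(self.cna.to_numpy(), (-1, 0, 1)).all():
            raise ValueError("cna codes must be in {-1, 0, +1}")
        if not np.isin(self.mutation.to_numpy(), (0, 1)).all():
            raise ValueError("mutation indicator must be 0/1")

    def gene_row(self, gene_id: str, samples: Sequence[str] | None = None):
        cna = self.cna.loc[gene_id]
        mut = self.mutation.loc[gene_id]
        if samples is not None:
            cna = cna[list(samples)]
            mut = mut[list(samples)]
        return cna.to_numpy(dtype=float), mut.to_numpy(dtype=float)

    def subset_samples(self, samples: Sequence[str]) -> "SomaticTable":
        samples = list(samples)
        return SomaticTable(self.cna[samples], self.mutation[samples])


@dataclass
class CisGeneResult:
    """Gene-level result of the permutation pass: the eGene call unit."""

    gene_id: str
    lead_variant: str
    n_variants_tested: int
    nominal_p_lead: float
    slope_lead: float
    beta_shape1: float
    beta_shape2: float
    n_permutations: int
    empirical_p: float
    adjusted_p: float
    q_value: float = np.nan
    afc_log2: float = np.nan
    distance: int = 0
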