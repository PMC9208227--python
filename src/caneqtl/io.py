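"""Readers and writers for the pipeline's on-disk formats.

Everything is tab-separated text with a header row; missing values are
encoded as ``NA``. Genotypes can also be read from a VCF carrying a ``DS``
(dosage) FORMAT field, and written as a minimal dosage VCF. Gene
annotation travels as BED (0-based half-open) and is converted to the
1-based inclusive coordinates used internally.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ExpressionSet, GenotypeMatrix, SomaticTable

__all__ = [
    "write_matrix_tsv",
    "read_matrix_tsv",
    "write_table_tsv",
    "read_table_tsv",
    "write_series_tsv",
    "read_series_tsv",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_gene_bed",
    "read_gene_bed",
    "read_vcf_dosages",
    "write_vcf_dosages",
    "read_expression",
    "read_somatic",
]

_FLOAT_FMT = "%.6g"


def write_matrix_tsv(frame: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label, na_rep="NA", float_format=_FLOAT_FMT)


def read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    frame.index.name = None
    return frame


def write_table_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format=_FLOAT_FMT)


def read_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")


def write_series_tsv(series: pd.Series, path: str | Path, index_label: str) -> None:
    series.to_frame().to_csv(path, sep="\t", index_label=index_label, na_rep="NA",
                             float_format=_FLOAT_FMT)


def read_series_tsv(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    return frame.iloc[:, 0]


def write_dosage_tsv(g: GenotypeMatrix, dosage_path: str | Path,
                     variant_path: str | Path) -> None:
    frame = pd.DataFrame(g.dosages.T, index=g.variants["id"].to_numpy(), columns=g.samples)
    write_matrix_tsv(frame, dosage_path, index_label="variant_id")
    write_table_tsv(g.variants, variant_path)


def read_dosage_tsv(dosage_path: str | Path, variant_path: str | Path) -> GenotypeMatrix:
    frame = read_matrix_tsv(dosage_path)
    variants = read_table_tsv(variant_path)
    if list(frame.index) != list(variants["id"]):
        raise ValueError("dosage rows and variant table out of order")
    return GenotypeMatrix(frame.to_numpy().T, variants, list(frame.columns))


def write_gene_bed(genes: pd.DataFrame, path: str | Path) -> None:
    """Internal 1-based inclusive coordinates -> BED 0-based half-open."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["id"],
            "score": 0,
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_gene_bed(path: str | Path) -> pd.DataFrame:
    """BED 0-based half-open -> internal 1-based inclusive coordinates."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    genes = pd.DataFrame(
        {
            "id": bed["name"],
            "chrom": bed["chrom"],
            "start": bed["start"] + 1,
            "end": bed["end"],
            "strand": bed["strand"],
        }
    ).set_index("id", drop=False)
    genes.index.name = None
    return genes


def read_expression(counts_path: str | Path, tpm_path: str | Path,
                    bed_path: str | Path) -> ExpressionSet:
    counts = read_matrix_tsv(counts_path).astype(np.int64)
    tpm = read_matrix_tsv(tpm_path)
    genes = read_gene_bed(bed_path)
    return ExpressionSet(counts=counts, tpm=tpm, genes=genes.reindex(counts.index))


def read_somatic(cna_path: str | Path, mut_path: str | Path) -> SomaticTable:
    return SomaticTable(
        cna=read_matrix_tsv(cna_path).astype(int),
        mutation=read_matrix_tsv(mut_path).astype(int),
    )


def write_vcf_dosages(g: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF with GT (hard call) and DS (dosage) per sample."""
    chroms = g.variants["chrom"].unique()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.samples) + "\n")
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, var in g.variants.iterrows():
            fields = [
                str(var["chrom"]), str(int(var["pos"])), str(var["id"]),
                str(var["ref"]), str(var["alt"]), ".", "PASS", ".", "GT:DS",
            ]
            col = g.dosages[:, j]
            for d in col:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_codes[int(round(d))]}:{d:.3f}")
            fh.write("\t".join(fields) + "\n")


def read_vcf_dosages(path: str | Path) -> GenotypeMatrix:
    """Read dosages from the ``DS`` FORMAT field of a VCF (via cyvcf2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    meta = []
    for rec in vcf:
        ds = rec.format("DS")
        if ds is None:
            raise ValueError(f"variant {rec.ID} lacks a DS field")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col[col < 0] = np.nan  # cyvcf2 encodes missing as negative sentinel
        rows.append(col)
        meta.append((rec.ID, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    variants = pd.DataFrame(meta, columns=["id", "chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(np.column_stack(rows), variants, samples)
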