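"""TSV / VCF readers and writers and packaged reference tables.

All tabular interchange is TSV: count matrices with genes as rows and
samples as columns, a sample sheet (sample_id, line, replicate, role),
gene length tables, allelic count tables, 5-column SNP tables and
annotation (gene, term) pairs. SNPs can also come from a VCF (biallelic
sites only); coordinates are 0-based half-open internally, 1-based on VCF
input.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

from .containers import CountMatrix

SNP_COLUMNS = ("chrom", "pos", "parent1_allele", "parent2_allele", "gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    required = {"sample_id", "line", "replicate"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    return sheet.set_index("sample_id")


def read_count_matrix(counts_path: str | Path,
                      sheet_path: str | Path) -> CountMatrix:
    return CountMatrix(read_counts(counts_path), read_sample_sheet(sheet_path))


def read_gene_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("length_bp")


def read_gene_set(path: str | Path) -> set:
    """One gene id per line; blank lines ignored."""
    text = Path(path).read_text()
    return {line.strip() for line in text.splitlines() if line.strip()}


def write_gene_set(genes: Iterable, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("annotation must have 2 columns (gene, term)")
    return df.iloc[:, :2].set_axis(["gene_id", "term_id"], axis=1)


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """5-column TSV: chrom, pos (0-based), parent1/2 alleles, gene_id."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table missing columns {sorted(missing)}")
    return df[list(SNP_COLUMNS)]


def read_snps_vcf(path: str | Path, gene_map: pd.DataFrame | None = None
                  ) -> pd.DataFrame:
    """Biallelic SNPs from a VCF; REF is the parent-1 allele, ALT parent 2.

    VCF positions are 1-based; the returned ``pos`` is 0-based. Multi-
    allelic and non-SNP records are skipped. ``gene_map`` (chrom, start,
    end, gene_id; half-open 0-based) assigns gene ids; without it the
    gene_id column is empty.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            rows.append({"chrom": rec.chrom, "pos": rec.pos - 1,
                         "parent1_allele": ref, "parent2_allele": alt,
                         "gene_id": ""})
    snps = pd.DataFrame(rows, columns=list(SNP_COLUMNS))
    if gene_map is not None and len(snps):
        for _, g in gene_map.iterrows():
            hit = ((snps["chrom"] == g["chrom"]) & (snps["pos"] >= g["start"])
                   & (snps["pos"] < g["end"]))
            snps.loc[hit, "gene_id"] = g["gene_id"]
    return snps


def read_read_profiles(path: str | Path) -> pd.DataFrame:
    """Long per-read SNP-match table: read_id, gene_id, observed,
    parent1_allele, parent2_allele (one row per covered SNP)."""
    df = pd.read_csv(path, sep="\t")
    required = {"read_id", "gene_id", "observed", "parent1_allele",
                "parent2_allele"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"read profile table missing columns {sorted(missing)}")
    return df


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"line", "value"}
    if not required <= set(df.columns):
        raise ValueError("phenotype table needs at least line and value")
    return df


def _packaged(name: str) -> pd.DataFrame:
    with resources.files("triplethet").joinpath("data", name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_ear_length_table() -> pd.DataFrame:
    """Printed ear-length means, SDs, LSD letters and MPH per line."""
    return _packaged("ear_length_phenotypes.tsv")


def load_library_read_stats() -> pd.DataFrame:
    """Printed per-library raw/clean/mapped read counts and rates."""
    return _packaged("library_read_stats.tsv")


def load_parental_range_table() -> pd.DataFrame:
    """Printed within/out-of-parental-range gene counts per triplet."""
    return _packaged("parental_range_counts.tsv")
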