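"""Library QC arithmetic, size factors, FPKM, replicate handling.

Normalization follows the median-of-ratios scheme: a per-gene reference is
the geometric mean of its counts across samples (restricted to genes with a
positive count in every sample), and each sample's size factor is the median
over those genes of count / reference. Expression per line is the mean of
its replicate samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from ._utils import as_count_frame, check_positive, round_half_up
from .containers import CountMatrix


@dataclass(frozen=True)
class LibraryQC:
    """Per-library read accounting with printed-precision rates (percent)."""

    sample_id: str
    raw_reads: int
    clean_reads: int
    mapped_reads: int
    retention_rate: float
    mapped_rate: float


def summarize_library_qc(
    raw: int, clean: int, mapped: int, sample_id: str = ""
) -> LibraryQC:
    """Retention = clean/raw, mapped rate = mapped/clean, half-up to 2 dp."""
    raw, clean, mapped = int(raw), int(clean), int(mapped)
    if not (0 <= mapped <= clean <= raw):
        raise ValueError("require 0 <= mapped <= clean <= raw")
    if raw == 0 or clean == 0:
        raise ZeroDivisionError("rates undefined for zero raw or clean reads")
    return LibraryQC(
        sample_id=sample_id,
        raw_reads=raw,
        clean_reads=clean,
        mapped_reads=mapped,
        retention_rate=round_half_up(100.0 * clean / raw),
        mapped_rate=round_half_up(100.0 * mapped / clean),
    )


def qc_table(stats: pd.DataFrame) -> pd.DataFrame:
    """QC report for a table with raw_reads / clean_reads / mapped_reads.

    Appends a ``Total`` row in which retention is the pooled ratio of totals
    while the mapped rate is the arithmetic mean of the per-library mapped
    rates (the convention such summary tables are printed with).
    """
    rows = [
        summarize_library_qc(
            row["raw_reads"], row["clean_reads"], row["mapped_reads"],
            sample_id=str(row.get("sample_id", i)),
        )
        for i, row in stats.reset_index(drop="sample_id" in stats.columns).iterrows()
    ]
    out = pd.DataFrame([r.__dict__ for r in rows])
    tot_raw = int(out["raw_reads"].sum())
    tot_clean = int(out["clean_reads"].sum())
    tot_mapped = int(out["mapped_reads"].sum())
    total = {
        "sample_id": "Total",
        "raw_reads": tot_raw,
        "clean_reads": tot_clean,
        "mapped_reads": tot_mapped,
        "retention_rate": round_half_up(100.0 * tot_clean / tot_raw),
        "mapped_rate": round_half_up(float(out["mapped_rate"].mean())),
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)


def estimate_size_factors(counts) -> pd.Series:
    """Median-of-ratios size factors over genes positive in every sample."""
    df = as_count_frame(counts)
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate size factors")
    arr = df.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError(
            "no gene has positive counts in every sample; cannot form the "
            "geometric-mean reference (a pseudo-reference fallback is not "
            "applied silently)"
        )
    sub = arr[all_positive]
    ref = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=df.columns, name="size_factor")


class SizeFactorNormalizer(BaseEstimator, TransformerMixin):
    """Median-of-ratios depth normalization as a fit/transform estimator.

    Operates on genes x samples frames (the orientation count matrices are
    distributed in). ``fit`` learns one positive factor per sample of the
    fitted matrix; ``transform`` divides each sample column by its factor.
    """

    def fit(self, X, y=None):
        self.size_factors_ = estimate_size_factors(X)
        return self

    def transform(self, X) -> pd.DataFrame:
        df = as_count_frame(X)
        sf = self.size_factors_.reindex(df.columns)
        if sf.isna().any():
            raise ValueError("transform called with samples absent at fit time")
        return df / sf

    def fit_transform(self, X, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X).transform(X)


def normalized_counts(cm: CountMatrix) -> pd.DataFrame:
    sf = cm.size_factors
    if sf is None:
        sf = estimate_size_factors(cm.counts)
    return cm.counts / sf


def compute_fpkm(counts, gene_lengths, mapped_totals) -> pd.DataFrame:
    """FPKM_gj = count_gj * 1e9 / (length_g * mapped_total_j)."""
    df = as_count_frame(counts)
    lengths = pd.Series(gene_lengths, dtype=float).reindex(df.index)
    if lengths.isna().any():
        raise ValueError("gene_lengths missing for some genes")
    check_positive(lengths.to_numpy(), "gene_lengths")
    totals = pd.Series(mapped_totals, dtype=float).reindex(df.columns)
    if totals.isna().any():
        raise ValueError("mapped_totals missing for some samples")
    check_positive(totals.to_numpy(), "mapped_totals")
    return df.mul(1e9).div(lengths, axis=0).div(totals, axis=1)


def replicate_correlation(
    cm: CountMatrix, line: str, size_factors: pd.Series | None = None
) -> float:
    """Pearson correlation of log2(normalized count + 1) between the two
    replicates of a line."""
    cols = cm.samples_for_line(line)
    if len(cols) != 2:
        raise ValueError(f"line {line!r} needs exactly 2 replicates, has {len(cols)}")
    sf = size_factors if size_factors is not None else cm.size_factors
    if sf is None:
        sf = estimate_size_factors(cm.counts)
    norm = cm.counts[cols] / sf[cols]
    x, y = np.log2(norm.iloc[:, 0] + 1.0), np.log2(norm.iloc[:, 1] + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant replicate")
    return float(np.corrcoef(x, y)[0, 1])


def average_replicates(
    values: pd.DataFrame, sample_lines: Mapping[str, str] | pd.Series,
    lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Arithmetic mean per gene per line over that line's replicate columns."""
    sample_lines = pd.Series(dict(sample_lines) if not isinstance(
        sample_lines, pd.Series) else sample_lines)
    groups: dict[str, list[str]] = {}
    for col in values.columns:
        if col not in sample_lines.index:
            raise KeyError(f"sample {col!r} has no line assignment")
        groups.setdefault(sample_lines[col], []).append(col)
    wanted = list(groups) if lines is None else list(lines)
    missing = [ln for ln in wanted if ln not in groups]
    if missing:
        raise KeyError(f"no replicates for line(s): {missing}")
    return pd.DataFrame(
        {ln: values[groups[ln]].mean(axis=1) for ln in wanted}, index=values.index
    )
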