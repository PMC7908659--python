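"""Mid-parent construction and hybrid expression-mode classification.

In an F1 hybrid each gene's expression is compared with the mid-parent (MP)
value, the average of its two parents. Genes indistinguishable from MP are
*additive*; genes significantly different from MP are *non-additive* and
fall into four named modes: high-parent dominance (tracks the higher
parent), low-parent dominance (tracks the lower parent), over-dominance
(significantly above the high parent) and under-dominance (significantly
below the low parent). Calls that fit none of the four are labelled
``ambiguous`` so the classifier is total.

The MP comparison is powered like any two-group comparison by building MP
pseudo-replicates: replicate i of MP is the rounded mean of the parents'
replicate-i normalized counts (size factor 1, already on the normalized
scale), and the same negative-binomial test is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._utils import round_half_up
from .containers import CountMatrix, Triplet
from .differential import nb_wald_test
from .quantification import average_replicates, estimate_size_factors

PATTERN_LABELS = (
    "additive",
    "high_parent_dominance",
    "low_parent_dominance",
    "over_dominance",
    "under_dominance",
    "ambiguous",
)


def build_midparent_pseudosamples(
    parent1_norm: pd.DataFrame, parent2_norm: pd.DataFrame
) -> pd.DataFrame:
    """Rounded per-replicate mean of two parents' normalized counts.

    Replicate i of parent 1 is paired with replicate i of parent 2; unequal
    replicate numbers are an error (no silent recycling).
    """
    if parent1_norm.shape[1] != parent2_norm.shape[1]:
        raise ValueError(
            "parents must have equal replicate numbers to build MP "
            f"pseudo-samples ({parent1_norm.shape[1]} vs {parent2_norm.shape[1]})"
        )
    if not parent1_norm.index.equals(parent2_norm.index):
        raise ValueError("parents must share one gene universe")
    mp = (parent1_norm.to_numpy(float) + parent2_norm.to_numpy(float)) / 2.0
    cols = [f"MP-{i + 1}" for i in range(parent1_norm.shape[1])]
    return pd.DataFrame(np.rint(mp), index=parent1_norm.index, columns=cols)


def call_nonadditive(
    hybrid_counts: pd.DataFrame,
    hybrid_size_factors: pd.Series,
    parent1_norm: pd.DataFrame,
    parent2_norm: pd.DataFrame,
    **test_kwargs,
) -> pd.DataFrame:
    """NB test of the hybrid against MP pseudo-samples.

    Non-additive iff the hybrid-vs-MP comparison meets the DEG criteria
    (p < 0.05 and |log2FC| > 1 by default). log2fc is hybrid over MP.
    """
    mp = build_midparent_pseudosamples(parent1_norm, parent2_norm)
    res = nb_wald_test(
        mp, hybrid_counts, None, hybrid_size_factors, **test_kwargs
    )
    return res.rename(columns={"base_mean_1": "mp_mean", "base_mean_2": "hybrid_mean",
                               "is_deg": "is_nonadditive"})


def classify_parental_range(line_means: pd.DataFrame, parent1: str, parent2: str,
                            hybrid: str) -> pd.Series:
    """Inclusive per-gene test of hybrid line mean within [low, high] parent."""
    lo = line_means[[parent1, parent2]].min(axis=1)
    hi = line_means[[parent1, parent2]].max(axis=1)
    h = line_means[hybrid]
    return ((h >= lo) & (h <= hi)).rename("within_parental_range")


def range_summary(within: pd.Series) -> dict:
    """Counts and half-up percentages of the within/out partition."""
    n = int(within.size)
    w = int(within.sum())
    return {
        "n_genes": n,
        "within": w,
        "out": n - w,
        "within_pct": round_half_up(100.0 * w / n),
        "out_pct": round_half_up(100.0 * (n - w) / n),
    }


def _classify_one(
    nonadd: bool,
    hybrid_val: float,
    high_val: float,
    low_val: float,
    sig_vs_high: bool,
    sig_vs_low: bool,
) -> str:
    if not nonadd:
        return "additive"
    if sig_vs_high and hybrid_val > high_val:
        return "over_dominance"
    if sig_vs_low and hybrid_val < low_val:
        return "under_dominance"
    if sig_vs_low and not sig_vs_high:
        return "high_parent_dominance"
    if sig_vs_high and not sig_vs_low:
        return "low_parent_dominance"
    return "ambiguous"


class HeterosisPatternClassifier(BaseEstimator):
    """Five-mode expression-pattern classifier for one triplet.

    ``fit`` takes a :class:`CountMatrix` containing (at least) the
    triplet's three lines and produces ``calls_``: per gene the MP and
    hybrid normalized means, the three pairwise test results, the pattern
    label, and the inclusive parental-range flag. Size factors are taken
    from the matrix or estimated on its samples.

    Parameters mirror the NB test: ``alpha`` and ``lfc_threshold`` are the
    joint call criteria, ``dispersion_mode`` selects the dispersion
    sharing scheme.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 1.0,
        dispersion_mode: str = "common",
        pseudocount: float = 1.0,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.dispersion_mode = dispersion_mode
        self.pseudocount = pseudocount

    def _test_kwargs(self) -> dict:
        return dict(
            alpha=self.alpha,
            lfc_threshold=self.lfc_threshold,
            dispersion_mode=self.dispersion_mode,
            pseudocount=self.pseudocount,
        )

    def fit(self, cm: CountMatrix, triplet: Triplet):
        sub = cm.subset_lines(triplet.lines)
        sf = sub.size_factors
        if sf is None:
            sf = estimate_size_factors(sub.counts)
        norm = sub.counts / sf
        p1 = norm[sub.samples_for_line(triplet.parent1)]
        p2 = norm[sub.samples_for_line(triplet.parent2)]
        hyb_cols = sub.samples_for_line(triplet.hybrid)
        hyb_raw = sub.counts[hyb_cols]
        hyb_sf = sf[hyb_cols]

        vs_mp = call_nonadditive(hyb_raw, hyb_sf, p1, p2, **self._test_kwargs())
        vs_p1 = nb_wald_test(np.rint(p1), hyb_raw, None, hyb_sf,
                             **self._test_kwargs())
        vs_p2 = nb_wald_test(np.rint(p2), hyb_raw, None, hyb_sf,
                             **self._test_kwargs())

        line_means = average_replicates(
            norm, sub.samples["line"], lines=list(triplet.lines)
        )
        p1_mean = line_means[triplet.parent1]
        p2_mean = line_means[triplet.parent2]
        hyb_mean = line_means[triplet.hybrid]
        p1_is_high = p1_mean >= p2_mean
        high_val = np.where(p1_is_high, p1_mean, p2_mean)
        low_val = np.where(p1_is_high, p2_mean, p1_mean)
        sig1 = vs_p1["is_deg"].to_numpy()
        sig2 = vs_p2["is_deg"].to_numpy()
        sig_vs_high = np.where(p1_is_high, sig1, sig2)
        sig_vs_low = np.where(p1_is_high, sig2, sig1)

        nonadd = vs_mp["is_nonadditive"].to_numpy()
        hv = hyb_mean.to_numpy()
        patterns = [
            _classify_one(nonadd[i], hv[i], high_val[i], low_val[i],
                          sig_vs_high[i], sig_vs_low[i])
            for i in range(len(hv))
        ]
        within = classify_parental_range(
            line_means, triplet.parent1, triplet.parent2, triplet.hybrid
        )
        self.calls_ = pd.DataFrame(
            {
                "mp_value": vs_mp["mp_mean"],
                "hybrid_value": vs_mp["hybrid_mean"],
                "parent_high_value": high_val,
                "parent_low_value": low_val,
                "p_vs_mp": vs_mp["p_value"],
                "log2fc_vs_mp": vs_mp["log2fc"],
                "is_nonadditive": nonadd,
                "sig_vs_high": sig_vs_high,
                "sig_vs_low": sig_vs_low,
                "pattern": pd.Categorical(patterns, categories=PATTERN_LABELS),
                "within_parental_range": within,
            },
            index=vs_mp.index,
        )
        self.triplet_ = triplet
        self.size_factors_ = sf
        self.nonadditive_genes_ = set(self.calls_.index[nonadd])
        self.range_summary_ = range_summary(within)
        return self
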