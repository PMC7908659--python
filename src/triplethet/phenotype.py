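"""Phenotype-level heterosis statistics.

Mid-parent heterosis (MPH) for a trait is 100 * (F1 - MP) / MP with MP the
mean of the two inbred parents' trait values. Group separation in trait
tables is reported as least-significant-difference (LSD) letters after a
one-way ANOVA, and qPCR validation uses the 2^-ddCt relative-expression
statistic against a reference gene and calibrator sample.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import round_half_up


def mph(f1_mean: float, parent1_mean: float, parent2_mean: float,
        ndigits: int = 2) -> float:
    """Mid-parent heterosis percentage, half-up rounded for reporting."""
    mp = (float(parent1_mean) + float(parent2_mean)) / 2.0
    if mp <= 0:
        raise ValueError("mid-parent value must be positive")
    return round_half_up(100.0 * (float(f1_mean) - mp) / mp, ndigits)


def mph_table(line_means: Mapping[str, float],
              crosses: Mapping[str, tuple[str, str]]) -> pd.Series:
    """MPH per hybrid from a dict of line means and hybrid -> parents map."""
    out = {}
    for hybrid, (p1, p2) in crosses.items():
        out[hybrid] = mph(line_means[hybrid], line_means[p1], line_means[p2])
    return pd.Series(out, name="mph_percent")


def _anova_mse(groups: Sequence[np.ndarray]) -> tuple[float, int]:
    """Residual mean square and error df of a one-way layout."""
    sse = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
    df = sum(len(g) for g in groups) - len(groups)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    return sse / df, df


def lsd_groups(table: pd.DataFrame, trait: str | None = None,
               alpha: float = 0.05,
               line_col: str = "line", value_col: str = "value",
               trait_col: str = "trait") -> pd.Series:
    """LSD letter labels per line at level ``alpha``.

    ``table`` holds replicate-level rows (line, value[, trait]). Lines are
    sorted by mean descending; two lines share a letter iff their mean
    difference is below LSD_ij = t(1 - alpha/2, df_e) * sqrt(MSE (1/n_i +
    1/n_j)). Letters come from the standard insert-and-absorb sweep over
    maximal runs of mutually non-separated lines.
    """
    df = table
    if trait is not None:
        df = df[df[trait_col] == trait]
    groups = {ln: sub[value_col].to_numpy(float)
              for ln, sub in df.groupby(line_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 lines")
    for ln, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"line {ln!r} has fewer than 2 replicates")
    mse, dfe = _anova_mse(list(groups.values()))
    tcrit = stats.t.ppf(1 - alpha / 2.0, dfe)

    lines = sorted(groups, key=lambda ln: -groups[ln].mean())
    means = np.array([groups[ln].mean() for ln in lines])
    ns = np.array([len(groups[ln]) for ln in lines])
    k = len(lines)

    def separated(i: int, j: int) -> bool:
        lsd = tcrit * np.sqrt(mse * (1.0 / ns[i] + 1.0 / ns[j]))
        return abs(means[i] - means[j]) >= lsd

    # maximal runs of consecutive, mutually non-separated lines
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and all(
            not separated(a, j + 1) for a in range(i, j + 1)
        ):
            j += 1
        if not runs or runs[-1][1] < j or runs[-1][0] > i:
            runs.append((i, j))
    # absorb runs nested in an earlier one
    runs = [r for r in runs if not any(
        o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]

    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = ["" for _ in range(k)]
    for letter, (lo, hi) in zip(alphabet, runs):
        for i in range(lo, hi + 1):
            letters[i] += letter
    return pd.Series(letters, index=pd.Index(lines, name=line_col),
                     name="lsd_letters")


def delta_delta_ct(ct_target_test: float, ct_ref_test: float,
                   ct_target_calibrator: float, ct_ref_calibrator: float
                   ) -> float:
    """Relative expression 2^-ddCt.

    ddCt = (Ct_target - Ct_ref) in the test sample minus the same
    difference in the calibrator sample.
    """
    for v in (ct_target_test, ct_ref_test, ct_target_calibrator,
              ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (
        ct_target_calibrator - ct_ref_calibrator)
    return float(2.0 ** (-ddct))
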