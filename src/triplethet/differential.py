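"""Two-group negative-binomial Wald test for differential expression.

Model
-----
Counts K_gj for gene g in sample j of group k follow NB with mean
mu_gk * s_j and variance mu_gk * s_j + alpha_g * (mu_gk * s_j)^2, where s_j
is the sample's size factor and alpha_g the gene's dispersion. The test
statistic is the log-ratio of normalized group means divided by its
delta-method standard error; p-values are two-sided normal tail areas.

Dispersion: with two replicates per group a purely per-gene moment
estimate is far too noisy to yield a calibrated Wald test, so by default a
single dispersion shared across genes is estimated by conditional maximum
likelihood (the likelihood of each group's counts given their sum, summed
over genes and groups, maximized in alpha — the qCML idea of edgeR's
common dispersion, applied to depth-adjusted rounded counts). Modes:
``"common"`` (default), ``"per_gene"`` (method of moments pooled across
the two groups), and ``"max"`` (the conservative elementwise max of the
two, in the spirit of early DESeq).

A gene is called differentially expressed when p < ``alpha`` and
|log2 fold-change| > ``lfc_threshold`` — raw p by design; BH-adjusted q is
reported alongside for transparency.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from ._utils import as_count_frame

_DISPERSION_MODES = ("common", "per_gene", "max")


def _moment_dispersions(
    norm: np.ndarray, groups: list[np.ndarray], inv_sf: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene pooled method-of-moments dispersion and overall mean.

    For normalized counts x = K/s, Var(x) = mu/s + alpha*mu^2, so a moment
    estimate from group residual variance v and group mean m is
    (v - m * mean(1/s)) / m^2, pooled over groups with df weights.
    """
    num = np.zeros(norm.shape[0])
    den = 0.0
    disp_num = np.zeros(norm.shape[0])
    for idx in groups:
        x = norm[:, idx]
        n = x.shape[1]
        m = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        poisson_part = m * inv_sf[idx].mean()
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - poisson_part) / np.maximum(m, 1e-300) ** 2, 0.0)
        disp_num += (n - 1) * a
        num += n * m
        den += n
    mu = num / den
    return disp_num / sum(len(idx) - 1 for idx in groups), mu


def _qcml_common_dispersion(
    group_counts: list[np.ndarray], floor: float
) -> float:
    """Common dispersion by conditional maximum likelihood.

    For counts y_1..y_n sharing one NB mean, the likelihood conditional on
    the sum z depends only on r = 1/alpha:
    sum_j lgamma(y_j + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r).
    Summed over genes and groups this removes the per-gene mean nuisance
    (whose plug-in MLE would bias alpha downward) and is maximized over a
    bounded log-alpha grid. Counts must be (near-)identically distributed
    within a group, so callers pass depth-adjusted rounded counts.
    """

    def neg_loglik(log_alpha: float) -> float:
        r = 1.0 / np.exp(log_alpha)
        total = 0.0
        for y in group_counts:
            n = y.shape[1]
            z = y.sum(axis=1)
            total += float(
                np.sum(special.gammaln(y + r))
                - y.shape[0] * n * special.gammaln(r)
                + y.shape[0] * special.gammaln(n * r)
                - np.sum(special.gammaln(z + n * r))
            )
        return -total

    res = optimize.minimize_scalar(
        neg_loglik, bounds=(np.log(max(floor, 1e-8)), np.log(50.0)),
        method="bounded", options={"xatol": 1e-4},
    )
    return float(max(np.exp(res.x), floor))


def nb_wald_test(
    counts1,
    counts2,
    size_factors1=None,
    size_factors2=None,
    *,
    alpha: float = 0.05,
    lfc_threshold: float = 1.0,
    dispersion_mode: str = "common",
    dispersion_floor: float = 1e-8,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Vectorized NB Wald test of group2 vs group1 over a shared gene set.

    Returns a frame indexed by gene with base_mean_1/2, log2fc, dispersion,
    se, p_value, q_value (BH), is_deg.
    """
    if dispersion_mode not in _DISPERSION_MODES:
        raise ValueError(f"dispersion_mode must be one of {_DISPERSION_MODES}")
    c1 = as_count_frame(counts1, "counts1")
    c2 = as_count_frame(counts2, "counts2")
    if not c1.index.equals(c2.index):
        raise ValueError("groups must share one gene universe")
    if c1.shape[1] < 2 or c2.shape[1] < 2:
        raise ValueError("need >=2 samples per group to estimate dispersion")

    sf1 = np.ones(c1.shape[1]) if size_factors1 is None else np.asarray(
        pd.Series(size_factors1).reindex(c1.columns), dtype=float)
    sf2 = np.ones(c2.shape[1]) if size_factors2 is None else np.asarray(
        pd.Series(size_factors2).reindex(c2.columns), dtype=float)
    if np.any(~np.isfinite(sf1)) or np.any(~np.isfinite(sf2)) or np.any(
            sf1 <= 0) or np.any(sf2 <= 0):
        raise ValueError("size factors must be positive and cover all samples")

    norm = np.column_stack([c1.to_numpy(float) / sf1, c2.to_numpy(float) / sf2])
    n1, n2 = c1.shape[1], c2.shape[1]
    idx1, idx2 = np.arange(n1), np.arange(n1, n1 + n2)
    inv_sf = np.concatenate([1.0 / sf1, 1.0 / sf2])

    alpha_hat, mu = _moment_dispersions(norm, [idx1, idx2], inv_sf)
    per_gene = np.maximum(alpha_hat, dispersion_floor)
    if dispersion_mode == "per_gene":
        disp = per_gene
    else:
        rounded = [np.rint(norm[:, idx1]).astype(np.int64),
                   np.rint(norm[:, idx2]).astype(np.int64)]
        common = _qcml_common_dispersion(rounded, dispersion_floor)
        disp = (np.full(norm.shape[0], common) if dispersion_mode == "common"
                else np.maximum(per_gene, common))

    m1 = norm[:, idx1].mean(axis=1)
    m2 = norm[:, idx2].mean(axis=1)
    pc = pseudocount
    log2fc = np.log2((m2 + pc) / (m1 + pc))

    # Delta-method variance of log mean, with the pseudocount carried into
    # the variance so all-zero groups keep a finite, conservative SE.
    var1 = (m1 + pc) / n1**2 * inv_sf[idx1].sum() + disp * (m1 + pc) ** 2 / n1
    var2 = (m2 + pc) / n2**2 * inv_sf[idx2].sum() + disp * (m2 + pc) ** 2 / n2
    se = np.sqrt(var1 / (m1 + pc) ** 2 + var2 / (m2 + pc) ** 2)
    delta = np.log(m2 + pc) - np.log(m1 + pc)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, delta / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    all_zero = (m1 == 0) & (m2 == 0)
    p[all_zero] = 1.0
    log2fc[all_zero] = 0.0

    q = multipletests(p, method="fdr_bh")[1]
    is_deg = (p < alpha) & (np.abs(log2fc) > lfc_threshold)
    return pd.DataFrame(
        {
            "base_mean_1": m1,
            "base_mean_2": m2,
            "log2fc": log2fc,
            "dispersion": disp,
            "se": se,
            "p_value": p,
            "q_value": q,
            "is_deg": is_deg,
        },
        index=c1.index.rename("gene_id"),
    )


class NegativeBinomialWaldTest(BaseEstimator):
    """Estimator wrapper around :func:`nb_wald_test`.

    ``fit(X, y)`` takes a genes x samples frame and per-sample group labels
    (exactly two distinct labels; the second in sorted order is "group 2",
    so log2fc is group2 over group1). Fitted attributes: ``results_``,
    ``groups_``, ``deg_genes_``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_threshold: float = 1.0,
        dispersion_mode: str = "common",
        dispersion_floor: float = 1e-8,
        pseudocount: float = 1.0,
    ):
        self.alpha = alpha
        self.lfc_threshold = lfc_threshold
        self.dispersion_mode = dispersion_mode
        self.dispersion_floor = dispersion_floor
        self.pseudocount = pseudocount

    def fit(self, X, y, size_factors=None):
        X = as_count_frame(X)
        y = pd.Series(np.asarray(y), index=X.columns)
        labels = sorted(y.unique())
        if len(labels) != 2:
            raise ValueError(f"need exactly 2 group labels, got {labels}")
        cols1 = X.columns[y == labels[0]]
        cols2 = X.columns[y == labels[1]]
        sf = None if size_factors is None else pd.Series(size_factors)
        self.results_ = nb_wald_test(
            X[cols1],
            X[cols2],
            None if sf is None else sf[cols1],
            None if sf is None else sf[cols2],
            alpha=self.alpha,
            lfc_threshold=self.lfc_threshold,
            dispersion_mode=self.dispersion_mode,
            dispersion_floor=self.dispersion_floor,
            pseudocount=self.pseudocount,
        )
        self.groups_ = tuple(labels)
        self.deg_genes_ = set(self.results_.index[self.results_["is_deg"]])
        return self


def test_differential(counts1, counts2, size_factors1=None, size_factors2=None,
                      **kwargs) -> pd.DataFrame:
    """Functional entry point; see :func:`nb_wald_test`."""
    return nb_wald_test(counts1, counts2, size_factors1, size_factors2, **kwargs)
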