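"""Allele-specific expression: read assignment and permutation calling.

In a hybrid, reads overlapping SNPs that distinguish the two parental
alleles can be assigned to a parent. A read counts for parent 1 only when
every informative SNP it covers matches the parent-1 allele (all-or-
nothing); reads covering no informative SNP are ambiguous and reads
matching both parents are conflicting — both are excluded from allelic
counts.

Per gene, the two allele-count columns are depth-normalized with
median-of-ratios size factors computed on that two-column matrix, and the
deviation of the normalized split from 1:1 is assessed by Monte-Carlo
sampling: B draws from Binomial(n, 1/2) with n the rounded normalized
total, two-sided in the distance from n/2, with the add-one p estimate
p = (1 + #{draws at least as extreme}) / (B + 1). Benjamini-Hochberg
across tested genes gives q; ASE is called at q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .quantification import estimate_size_factors

ASSIGN_PARENT1 = "parent1"
ASSIGN_PARENT2 = "parent2"
ASSIGN_AMBIGUOUS = "ambiguous"
ASSIGN_CONFLICTING = "conflicting"


@dataclass(frozen=True)
class SnpSite:
    """One covered SNP: observed base plus the two parental alleles.

    ``position`` is 0-based; a site where the parental alleles agree is
    non-informative and ignored.
    """

    position: int
    observed: str
    parent1_allele: str
    parent2_allele: str

    @property
    def informative(self) -> bool:
        return self.parent1_allele != self.parent2_allele


@dataclass
class ReadSnpProfile:
    read_id: str
    gene_id: str
    sites: tuple[SnpSite, ...]


def assign_read(profile: ReadSnpProfile) -> str:
    """Assign a read to a parent from its covered SNP matches."""
    hits1 = hits2 = 0
    for site in profile.sites:
        if not site.informative:
            continue
        if site.observed == site.parent1_allele:
            hits1 += 1
        elif site.observed == site.parent2_allele:
            hits2 += 1
        # a base matching neither allele carries no parental information
    if hits1 and hits2:
        return ASSIGN_CONFLICTING
    if hits1:
        return ASSIGN_PARENT1
    if hits2:
        return ASSIGN_PARENT2
    return ASSIGN_AMBIGUOUS


def assign_reads(profiles: Iterable[ReadSnpProfile]) -> pd.DataFrame:
    rows = [
        (p.read_id, p.gene_id, assign_read(p)) for p in profiles
    ]
    return pd.DataFrame(rows, columns=["read_id", "gene_id", "assignment"])


def assign_reads_table(table: pd.DataFrame) -> pd.DataFrame:
    """Assign reads from a long site table.

    Expects columns read_id, gene_id, observed, parent1_allele,
    parent2_allele (one row per covered SNP; a read with no rows cannot be
    represented and would be ambiguous anyway).
    """
    t = table.copy()
    informative = t["parent1_allele"] != t["parent2_allele"]
    t = t[informative]
    t["m1"] = t["observed"] == t["parent1_allele"]
    t["m2"] = t["observed"] == t["parent2_allele"]
    g = t.groupby(["read_id", "gene_id"], sort=False)[["m1", "m2"]].sum()
    cond = [
        (g["m1"] > 0) & (g["m2"] > 0),
        g["m1"] > 0,
        g["m2"] > 0,
    ]
    out = np.select(cond, [ASSIGN_CONFLICTING, ASSIGN_PARENT1, ASSIGN_PARENT2],
                    default=ASSIGN_AMBIGUOUS)
    res = g.reset_index()[["read_id", "gene_id"]]
    res["assignment"] = out
    return res


def aggregate_allelic_counts(assignments: pd.DataFrame,
                             genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Tally parent1/parent2 reads per gene; ambiguous/conflicting dropped."""
    counts = (
        assignments.groupby("gene_id")["assignment"]
        .value_counts()
        .unstack(fill_value=0)
    )
    out = pd.DataFrame(index=counts.index)
    out["n1"] = counts.get(ASSIGN_PARENT1, 0)
    out["n2"] = counts.get(ASSIGN_PARENT2, 0)
    if genes is not None:
        out = out.reindex(list(genes), fill_value=0)
    out.index.name = "gene_id"
    return out


class PermutationASECaller(BaseEstimator):
    """Monte-Carlo 1:1-deviation test with BH false-discovery control.

    ``fit(X)`` expects a frame with integer columns ``n1``/``n2`` indexed
    by gene. Fitted attribute ``results_`` adds n1_norm, n2_norm, tested,
    perm_p, fdr_q, is_ase, biased_parent. Genes below ``min_depth``
    normalized informative reads are marked untested (no p), never
    silently given p = 1.
    """

    def __init__(
        self,
        n_permutations: int = 1000,
        min_depth: int = 10,
        fdr_threshold: float = 0.05,
        random_state: int | None = None,
        normalize: bool = True,
        chunk_size: int = 4096,
    ):
        self.n_permutations = n_permutations
        self.min_depth = min_depth
        self.fdr_threshold = fdr_threshold
        self.random_state = random_state
        self.normalize = normalize
        self.chunk_size = chunk_size

    def fit(self, X, y=None):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        df = pd.DataFrame(X)
        if not {"n1", "n2"}.issubset(df.columns):
            raise ValueError("allelic table needs columns n1 and n2")
        if (df[["n1", "n2"]] < 0).to_numpy().any():
            raise ValueError("allelic counts must be non-negative")
        rng = np.random.default_rng(self.random_state)

        res = df[["n1", "n2"]].astype(float).copy()
        if self.normalize:
            sf = estimate_size_factors(res.rename(columns={"n1": "a1", "n2": "a2"}))
        else:
            sf = pd.Series([1.0, 1.0], index=["a1", "a2"], name="size_factor")
        res["n1_norm"] = res["n1"] / sf.iloc[0]
        res["n2_norm"] = res["n2"] / sf.iloc[1]
        total = res["n1_norm"] + res["n2_norm"]
        tested = (total >= self.min_depth).to_numpy()
        res["tested"] = tested

        n = np.rint(total.to_numpy()).astype(np.int64)
        # symmetric in (n1, n2): equals |n1_norm - total/2|
        d_obs = 0.5 * np.abs(res["n1_norm"].to_numpy() - res["n2_norm"].to_numpy())
        B = int(self.n_permutations)
        perm_p = np.full(len(res), np.nan)
        idx = np.flatnonzero(tested)
        # small numeric slack so a draw exactly as extreme always counts
        slack = 1e-9
        for start in range(0, idx.size, self.chunk_size):
            sel = idx[start:start + self.chunk_size]
            draws = rng.binomial(n[sel][:, None], 0.5, size=(sel.size, B))
            extreme = np.abs(draws - n[sel][:, None] / 2.0) >= (
                d_obs[sel][:, None] - slack
            )
            perm_p[sel] = (1.0 + extreme.sum(axis=1)) / (B + 1.0)
        res["perm_p"] = perm_p

        q = np.full(len(res), np.nan)
        if idx.size:
            q[idx] = multipletests(perm_p[idx], method="fdr_bh")[1]
        res["fdr_q"] = q
        res["is_ase"] = np.where(tested, q < self.fdr_threshold, False)
        res["biased_parent"] = np.select(
            [res["n1_norm"] > res["n2_norm"], res["n2_norm"] > res["n1_norm"]],
            ["parent1", "parent2"],
            default="",
        )
        res.loc[~res["is_ase"].astype(bool), "biased_parent"] = ""
        res["n1"] = df["n1"].to_numpy()
        res["n2"] = df["n2"].to_numpy()
        self.size_factors_ = sf
        self.results_ = res
        self.ase_genes_ = set(res.index[res["is_ase"].astype(bool)])
        return self


def call_ase(
    allelic: pd.DataFrame,
    n_permutations: int = 1000,
    min_depth: int = 10,
    fdr_threshold: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Functional entry point; see :class:`PermutationASECaller`."""
    caller = PermutationASECaller(
        n_permutations=n_permutations,
        min_depth=min_depth,
        fdr_threshold=fdr_threshold,
        random_state=seed,
    )
    return caller.fit(allelic).results_
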