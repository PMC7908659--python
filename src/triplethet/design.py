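"""Multi-triplet comparative set logic and hypergeometric enrichment.

The joint netted design means each focal parent appears in three triplets,
so gene sets called per triplet can be intersected to isolate effects that
travel with a parent across genetic backgrounds:

* *candidate additive genes* for a focal parent pair (A, B): genes DE
  between the corresponding hybrids AxC vs BxC in two backgrounds C, and
  also DE between A and B themselves — the chain of intersections that
  pins expression differences to the focal parents.
* *candidate heterosis genes* for a focal parent A: genes non-additively
  expressed in all three hybrids that have A as a parent; the set shared
  by two focal parents is the intersection of their results.

Enrichment is annotation-agnostic: a user-supplied gene-to-term mapping is
scored per term with the hypergeometric upper tail P(X >= k | N, K, n).
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import Triplet, TripletDesign  # noqa: F401  (re-export)


def intersect_sets(sets: Sequence[Iterable]) -> set:
    """Exact intersection of two or more gene sets."""
    sets = [set(s) for s in sets]
    if len(sets) < 2:
        raise ValueError("need at least 2 sets to intersect")
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def venn_region_counts(sets: Mapping[str, Iterable]) -> pd.DataFrame:
    """Cardinality of every non-empty Venn region for up to 5 sets.

    A region is identified by the subset of labels whose sets contain its
    members exclusively; all 2^k - 1 regions are reported.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 5:
        raise ValueError("venn regions supported for 2-5 sets")
    as_sets = {lab: set(s) for lab, s in sets.items()}
    union = set().union(*as_sets.values())
    rows = []
    for r in range(1, len(labels) + 1):
        for inside in combinations(labels, r):
            members = intersect_sets([as_sets[lab] for lab in inside]) if len(
                inside) > 1 else set(as_sets[inside[0]])
            for lab in labels:
                if lab not in inside:
                    members = members - as_sets[lab]
            rows.append({
                "region": "&".join(inside),
                "n_sets": r,
                "count": len(members),
            })
    df = pd.DataFrame(rows)
    assert df["count"].sum() == len(union)
    return df


def candidate_additive_genes(
    hybrid_deg_sets: Mapping[str, Iterable],
    parent_deg_set: Iterable,
) -> set:
    """Chain intersection: hybrid-vs-hybrid DEG sets, then parent-vs-parent.

    ``hybrid_deg_sets`` maps comparison labels (e.g. "T121xPH4CV|T126xPH4CV")
    to DEG sets; exactly two are expected. Returns the genes DE in both
    hybrid comparisons and between the two focal parents.
    """
    if len(hybrid_deg_sets) != 2:
        raise ValueError(
            "expected DEG sets for exactly 2 hybrid-vs-hybrid comparisons, "
            f"got {sorted(hybrid_deg_sets)}"
        )
    overlap = intersect_sets(list(hybrid_deg_sets.values()))
    return overlap & set(parent_deg_set)


def candidate_heterosis_genes(
    design: TripletDesign,
    nonadditive_sets: Mapping[str, Iterable],
    focal_parent: str,
) -> set:
    """Genes non-additive in every hybrid carrying the focal parent.

    ``nonadditive_sets`` maps hybrid ids to non-additive gene sets; the
    three triplets containing ``focal_parent`` must all be present.
    """
    triplets = design.triplets_with_parent(focal_parent)
    if len(triplets) < 3:
        raise ValueError(
            f"focal parent {focal_parent!r} appears in {len(triplets)} "
            "triplets; need at least 3"
        )
    missing = [t.hybrid for t in triplets if t.hybrid not in nonadditive_sets]
    if missing:
        raise KeyError(f"missing non-additive sets for hybrids: {missing}")
    return intersect_sets([nonadditive_sets[t.hybrid] for t in triplets])


def shared_heterosis_genes(result_a: Iterable, result_b: Iterable) -> set:
    """Candidate heterosis genes common to two focal parents."""
    return set(result_a) & set(result_b)


def enrich(
    gene_set: Iterable,
    annotation: Mapping[str, Iterable] | pd.DataFrame,
    universe: Iterable,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene set per term.

    ``annotation`` is either a mapping gene -> terms or a 2-column frame
    (gene, term). Terms with no annotated gene in the universe are skipped.
    Returns all scored terms sorted by p with a rank column and BH q.
    """
    genes = set(gene_set)
    uni = set(universe)
    if not genes <= uni:
        raise ValueError("gene set must be a subset of the universe")
    if isinstance(annotation, pd.DataFrame):
        gene_col, term_col = annotation.columns[:2]
        pairs = annotation[[gene_col, term_col]].itertuples(index=False)
    else:
        pairs = ((g, t) for g, terms in annotation.items() for t in terms)
    term_members: dict[str, set] = {}
    for g, t in pairs:
        if g in uni:
            term_members.setdefault(t, set()).add(g)

    N, n = len(uni), len(genes)
    rows = []
    for term, members in sorted(term_members.items()):
        K = len(members)
        if K == 0:
            continue
        k = len(members & genes)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term, "k": k, "K": K, "n": n, "N": N,
                     "p_value": min(p, 1.0)})
    if not rows:
        return pd.DataFrame(
            columns=["term_id", "k", "K", "n", "N", "p_value", "q_value", "rank"]
        )
    df = pd.DataFrame(rows)
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df = df.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(
        drop=True)
    df["rank"] = df.index + 1
    return df


def top_terms(results: pd.DataFrame, alpha: float = 0.05, top: int = 10
              ) -> pd.DataFrame:
    """The reported view: terms at raw p < alpha, best ``top`` by rank."""
    return results[results["p_value"] < alpha].head(top).reset_index(drop=True)
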