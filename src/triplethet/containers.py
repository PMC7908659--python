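"""In-memory containers for the parent-hybrid triplet design.

A *triplet* is a (parent1, parent2, F1 hybrid) unit. Four inbred parents
crossed in a half-diallel without reciprocals yield six hybrids; every line
then participates in several triplets (a "joint netted pattern"), which is
what makes multi-triplet comparative set logic possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from ._utils import as_count_frame

SAMPLE_SHEET_COLUMNS = ("sample_id", "line", "replicate", "role")


def hybrid_name(parent1: str, parent2: str) -> str:
    return f"{parent1}x{parent2}"


@dataclass(frozen=True)
class Triplet:
    parent1: str
    parent2: str
    hybrid: str

    @property
    def lines(self) -> tuple[str, str, str]:
        return (self.parent1, self.parent2, self.hybrid)

    def contains_parent(self, line: str) -> bool:
        return line in (self.parent1, self.parent2)


@dataclass
class TripletDesign:
    """Registry of parent lines and their parent1-parent2-hybrid triplets."""

    parents: tuple[str, ...]
    triplets: tuple[Triplet, ...]

    def __post_init__(self) -> None:
        if len(set(self.parents)) != len(self.parents):
            raise ValueError("duplicate parent line identifiers")
        seen = set()
        for t in self.triplets:
            if t.parent1 == t.parent2:
                raise ValueError(f"self-cross in triplet {t}")
            if t.parent1 not in self.parents or t.parent2 not in self.parents:
                raise ValueError(f"triplet {t} references unknown parent")
            key = frozenset((t.parent1, t.parent2))
            if key in seen:
                raise ValueError(f"reciprocal or duplicate cross {t}")
            seen.add(key)

    @classmethod
    def half_diallel(cls, parents: Sequence[str]) -> "TripletDesign":
        """All unordered parent pairs, no reciprocals, no self-crosses."""
        parents = tuple(parents)
        trips = tuple(
            Triplet(a, b, hybrid_name(a, b)) for a, b in combinations(parents, 2)
        )
        return cls(parents=parents, triplets=trips)

    @property
    def hybrids(self) -> tuple[str, ...]:
        return tuple(t.hybrid for t in self.triplets)

    @property
    def lines(self) -> tuple[str, ...]:
        return self.parents + self.hybrids

    def triplets_with_parent(self, line: str) -> list[Triplet]:
        return [t for t in self.triplets if t.contains_parent(line)]

    def triplet_for_hybrid(self, hybrid: str) -> Triplet:
        for t in self.triplets:
            if t.hybrid == hybrid:
                return t
        raise KeyError(f"no triplet with hybrid {hybrid!r}")


@dataclass
class CountMatrix:
    """Genes x samples integer counts plus a sample sheet.

    ``samples`` is indexed by sample_id with columns line / replicate / role
    (role in {parent, hybrid}); every count column must appear in the sheet.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    size_factors: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.counts = as_count_frame(self.counts)
        samples = pd.DataFrame(self.samples)
        if samples.index.name != "sample_id":
            if "sample_id" in samples.columns:
                samples = samples.set_index("sample_id")
            else:
                samples.index.name = "sample_id"
        missing = set(self.counts.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples missing from sheet: {sorted(missing)}")
        if samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in sheet")
        self.samples = samples.loc[list(self.counts.columns)]
        if self.size_factors is not None:
            sf = pd.Series(self.size_factors)
            if not (sf.reindex(self.counts.columns).notna()).all():
                raise ValueError("size_factors must cover every sample")
            if (sf <= 0).any():
                raise ValueError("size_factors must be positive")
            self.size_factors = sf.reindex(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def lines(self) -> list[str]:
        return list(dict.fromkeys(self.samples["line"]))

    def samples_for_line(self, line: str) -> list[str]:
        ids = list(self.samples.index[self.samples["line"] == line])
        if not ids:
            raise KeyError(f"no samples for line {line!r}")
        return ids

    def counts_for_line(self, line: str) -> pd.DataFrame:
        return self.counts[self.samples_for_line(line)]

    def subset_lines(self, lines: Iterable[str]) -> "CountMatrix":
        cols = [s for line in lines for s in self.samples_for_line(line)]
        sf = None if self.size_factors is None else self.size_factors[cols]
        return CountMatrix(self.counts[cols], self.samples.loc[cols], sf)
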