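"""Allele-resolved synthetic parent-hybrid triplet count data.

The generator emulates a half-diallel study design: four inbred parents,
six F1 hybrids (no reciprocals), two biological replicates per line, and
per-library sequencing depths on the scale of 13-22 million fragments.
Counts are negative-binomial with variance mu + alpha * mu^2.

Planted structure, with per-gene truth labels:

* **DEGs** — a fraction of genes get one parent line's mean multiplied by
  2^(+-deg_log2fc_magnitude), making them DE between that parent and every
  other line.
* **Non-additive genes** — by default a hybrid's expected mean is exactly
  the mid-parent of its parents' means; planted non-additive genes have
  the mean moved to a mode: the high parent (high-parent dominance), the
  low parent (low-parent dominance), 2^margin above the high parent
  (over-dominance) or 2^margin below the low parent (under-dominance).
  A configurable share is planted in *every* hybrid ("universal" genes,
  restricted to over/under-dominance so the deviation exists in every
  background); the rest in one random hybrid each. Dominance-mode genes
  additionally receive a parental split so high and low parent are
  separable.
* **cis-ASE genes** — the allelic split of a hybrid's informative reads
  is Binomial(n, 0.5) except for planted genes, which use
  Binomial(n, cis_bias) in every hybrid (cis effects travel with the
  allele). The informative fraction of a gene's reads is Beta-distributed
  across genes; allelic reads never exceed the gene's total count.

DEG, non-additive and cis-ASE planting use disjoint-by-construction gene
draws for the first two (so truth labels are unambiguous) and an
independent draw for ASE (so ASE/non-additive overlap is at independence
level).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CountMatrix, TripletDesign

NONADDITIVE_MODES = (
    "high_parent_dominance",
    "low_parent_dominance",
    "over_dominance",
    "under_dominance",
)


@dataclass
class SimulationConfig:
    """Study-design and distributional knobs of the generator.

    Defaults emulate the transcriptome study design the package targets:
    4 parents in a half-diallel (6 hybrids), 2 replicates, ~25k expressed
    genes, library depths uniform on 13-22 million.
    """

    n_genes: int = 25199
    n_replicates: int = 2
    parents: tuple[str, ...] = ("T121", "T126", "PH4CV", "PH6WC")
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    dispersion: float = 0.05
    library_sizes: dict[str, float] | None = None
    library_size_range: tuple[float, float] = (13e6, 22e6)
    frac_deg: float = 0.1
    deg_log2fc_magnitude: float = 2.0
    frac_nonadditive: float = 0.05
    nonadditive_mode_mix: dict[str, float] = field(
        default_factory=lambda: {m: 0.25 for m in NONADDITIVE_MODES}
    )
    frac_nonadditive_universal: float = 0.2
    nonadditive_margin_log2: float = 0.5
    dominance_parent_log2sep: float = 3.0
    frac_cis_ase: float = 0.1
    cis_bias: float = 0.8
    informative_mean: float = 0.3
    informative_concentration: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_replicates"):
            v = getattr(self, name)
            if isinstance(v, bool) or not isinstance(v, (int, np.integer)):
                raise TypeError(f"{name} must be an integer")
            if v < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_deg", "frac_nonadditive", "frac_cis_ase",
                     "frac_nonadditive_universal", "cis_bias",
                     "informative_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if set(self.nonadditive_mode_mix) != set(NONADDITIVE_MODES):
            raise ValueError(f"mode mix must have keys {NONADDITIVE_MODES}")
        if any(p < 0 for p in self.nonadditive_mode_mix.values()):
            raise ValueError("mode mix proportions must be non-negative")
        if abs(sum(self.nonadditive_mode_mix.values()) - 1.0) > 1e-9:
            raise ValueError("nonadditive_mode_mix must sum to 1 (tol 1e-9)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.library_sizes is not None and any(
                v <= 0 for v in self.library_sizes.values()):
            raise ValueError("library_sizes must be positive")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if len(self.parents) < 2:
            raise ValueError("need at least 2 parent lines")

    @property
    def design(self) -> TripletDesign:
        return TripletDesign.half_diallel(self.parents)


@dataclass
class SyntheticDataset:
    """Counts, allelic counts, lengths and the planted truth."""

    counts: CountMatrix
    allelic_counts: pd.DataFrame  # long: hybrid, gene_id, n1, n2, total
    gene_lengths: pd.Series
    truth: pd.DataFrame  # per gene
    truth_patterns: pd.DataFrame  # long: gene_id, hybrid, mode, true_log2_dev
    expected_means: pd.DataFrame  # genes x lines expected normalized means
    config: SimulationConfig

    def deg_truth(self, parent_a: str, parent_b: str) -> pd.Series:
        """Planted DE status between two lines (parent effect in the pair)."""
        eff = self.truth["parent_effect_line"]
        return (eff.isin([parent_a, parent_b]) & (eff != "")).rename("is_deg")

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.counts.to_csv(out / "counts.tsv", sep="\t")
        self.counts.samples.to_csv(out / "sample_sheet.tsv", sep="\t")
        self.allelic_counts.to_csv(out / "allelic_counts.tsv", sep="\t",
                                   index=False)
        self.gene_lengths.rename("length_bp").to_csv(
            out / "gene_lengths.tsv", sep="\t")
        self.truth.to_csv(out / "truth.tsv", sep="\t")
        self.truth_patterns.to_csv(out / "truth_patterns.tsv", sep="\t",
                                   index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """NB with variance mean + dispersion * mean^2 (size r = 1/dispersion)."""
    r = 1.0 / dispersion
    out = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
    return out


def simulate_triplets(config: SimulationConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    design = config.design
    G = config.n_genes
    genes = pd.Index([f"gene{i:05d}" for i in range(G)], name="gene_id")
    parents = list(design.parents)
    hybrids = list(design.hybrids)
    lines = parents + hybrids

    # baseline relative expression and per-parent multipliers
    weights = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, G)
    mult = pd.DataFrame(1.0, index=genes, columns=parents)

    order = rng.permutation(G)
    n_deg = int(round(config.frac_deg * G))
    n_na = int(round(config.frac_nonadditive * G))
    if n_deg + n_na > G:
        raise ValueError("frac_deg + frac_nonadditive exceed the gene count")
    deg_idx = order[:n_deg]
    na_idx = order[n_deg:n_deg + n_na]

    truth = pd.DataFrame(
        {
            "is_deg": False,
            "parent_effect_line": "",
            "parent_effect_log2": 0.0,
            "nonadd_mode": "",
            "nonadd_universal": False,
            "nonadd_hybrids": "",
            "is_cis_ase": False,
            "allele1_prob": 0.5,
        },
        index=genes,
    )

    deg_line = rng.integers(0, len(parents), n_deg)
    deg_dir = rng.choice([-1.0, 1.0], n_deg)
    for g, li, d in zip(deg_idx, deg_line, deg_dir):
        lfc = d * config.deg_log2fc_magnitude
        mult.iloc[g, li] = 2.0 ** lfc
        truth.iloc[g, truth.columns.get_loc("is_deg")] = True
        truth.iloc[g, truth.columns.get_loc("parent_effect_line")] = parents[li]
        truth.iloc[g, truth.columns.get_loc("parent_effect_log2")] = lfc

    # non-additive planting
    modes = list(config.nonadditive_mode_mix)
    probs = np.array([config.nonadditive_mode_mix[m] for m in modes])
    od_modes = [m for m in modes if m in ("over_dominance", "under_dominance")]
    od_probs = np.array([config.nonadditive_mode_mix[m] for m in od_modes])
    na_records: list[tuple[int, str, list[str]]] = []
    for g in na_idx:
        universal = (rng.random() < config.frac_nonadditive_universal
                     and od_probs.sum() > 0)
        if universal:
            mode = str(rng.choice(od_modes, p=od_probs / od_probs.sum()))
            planted = hybrids
        else:
            mode = str(rng.choice(modes, p=probs))
            planted = [hybrids[rng.integers(0, len(hybrids))]]
        if mode in ("high_parent_dominance", "low_parent_dominance"):
            # give the gene a parental split so high/low are separable
            li = int(rng.integers(0, len(parents)))
            mult.iloc[g, li] = 2.0 ** config.dominance_parent_log2sep
            truth.iloc[g, truth.columns.get_loc("parent_effect_line")] = (
                parents[li])
            truth.iloc[g, truth.columns.get_loc("parent_effect_log2")] = (
                config.dominance_parent_log2sep)
        truth.iloc[g, truth.columns.get_loc("nonadd_mode")] = mode
        truth.iloc[g, truth.columns.get_loc("nonadd_universal")] = universal
        truth.iloc[g, truth.columns.get_loc("nonadd_hybrids")] = ";".join(
            planted)
        na_records.append((g, mode, planted))

    # expected normalized means per line
    mean_by_line = pd.DataFrame(index=genes, columns=lines, dtype=float)
    for p in parents:
        mean_by_line[p] = weights * mult[p].to_numpy()
    for t in design.triplets:
        m1 = mean_by_line[t.parent1].to_numpy()
        m2 = mean_by_line[t.parent2].to_numpy()
        mean_by_line[t.hybrid] = (m1 + m2) / 2.0
    margin = 2.0 ** config.nonadditive_margin_log2
    pattern_rows = []
    for g, mode, planted in na_records:
        for h in planted:
            t = design.triplet_for_hybrid(h)
            m1 = mean_by_line.iloc[g][t.parent1]
            m2 = mean_by_line.iloc[g][t.parent2]
            hi, lo = max(m1, m2), min(m1, m2)
            if mode == "high_parent_dominance":
                val = hi
            elif mode == "low_parent_dominance":
                val = lo
            elif mode == "over_dominance":
                val = hi * margin
            else:
                val = lo / margin
            mean_by_line.loc[genes[g], h] = val
    for g, mode, planted in na_records:
        for h in planted:
            t = design.triplet_for_hybrid(h)
            mp = (mean_by_line.iloc[g][t.parent1]
                  + mean_by_line.iloc[g][t.parent2]) / 2.0
            dev = np.log2(mean_by_line.iloc[g][h] / mp) if mp > 0 else 0.0
            pattern_rows.append({"gene_id": genes[g], "hybrid": h,
                                 "mode": mode, "true_log2_dev": dev})
    truth_patterns = pd.DataFrame(
        pattern_rows, columns=["gene_id", "hybrid", "mode", "true_log2_dev"])

    # cis-ASE planting: independent draw
    cis = rng.random(G) < config.frac_cis_ase
    truth["is_cis_ase"] = cis
    truth.loc[cis, "allele1_prob"] = config.cis_bias

    # samples and library sizes
    sample_rows = []
    for line in lines:
        role = "parent" if line in parents else "hybrid"
        for r in range(1, config.n_replicates + 1):
            sample_rows.append({"sample_id": f"{line}-{r}", "line": line,
                                "replicate": r, "role": role})
    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    if config.library_sizes is not None:
        missing = set(samples.index) - set(config.library_sizes)
        if missing:
            raise ValueError(f"library_sizes missing samples: {sorted(missing)}")
        lib = np.array([config.library_sizes[s] for s in samples.index])
    else:
        lo, hi = config.library_size_range
        lib = rng.uniform(lo, hi, len(samples))

    # counts: scale by the baseline weight total so planted fold-changes
    # are exact on the mean scale (library totals stay approximate)
    W = weights.sum()
    counts = np.zeros((G, len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples.index):
        line = samples.iloc[j]["line"]
        mu = lib[j] * mean_by_line[line].to_numpy() / W
        counts[:, j] = _nb_draw(rng, mu, config.dispersion)
    cm = CountMatrix(pd.DataFrame(counts, index=genes,
                                  columns=samples.index), samples)

    gene_lengths = pd.Series(
        np.rint(np.exp(rng.uniform(np.log(500), np.log(5000), G))).astype(int),
        index=genes, name="length_bp",
    )

    # allelic counts per hybrid (aggregated over replicates)
    a_mean = config.informative_mean * config.informative_concentration
    b_mean = (1 - config.informative_mean) * config.informative_concentration
    phi = rng.beta(a_mean, b_mean, G)
    p1prob = truth["allele1_prob"].to_numpy()
    allelic_rows = []
    for t in design.triplets:
        cols = [s for s in samples.index
                if samples.loc[s, "line"] == t.hybrid]
        tot = cm.counts[cols].to_numpy().sum(axis=1)
        n_inf = rng.binomial(tot, phi)
        n1 = rng.binomial(n_inf, p1prob)
        allelic_rows.append(pd.DataFrame({
            "hybrid": t.hybrid, "gene_id": genes,
            "n1": n1, "n2": n_inf - n1, "total_reads": tot,
        }))
    allelic = pd.concat(allelic_rows, ignore_index=True)

    return SyntheticDataset(
        counts=cm,
        allelic_counts=allelic,
        gene_lengths=gene_lengths,
        truth=truth,
        truth_patterns=truth_patterns,
        expected_means=mean_by_line,
        config=config,
    )


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
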