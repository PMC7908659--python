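"""End-to-end orchestration: simulate -> normalize -> DEG -> patterns ->
ASE -> comparative sets -> report.

One run seed fans out deterministically to per-stage child seeds, so
toggling stages never changes the data another stage sees, and identical
config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import round_half_up, spawn_seed
from .ase import PermutationASECaller
from .containers import TripletDesign
from .differential import nb_wald_test
from .design import (candidate_additive_genes, candidate_heterosis_genes,
                     shared_heterosis_genes)
from .patterns import HeterosisPatternClassifier
from .quantification import (average_replicates, compute_fpkm,
                             estimate_size_factors, replicate_correlation)
from .simulate import SimulationConfig, simulate_triplets

STAGES = ("simulate", "normalize", "deg", "patterns", "ase", "compare")


@dataclass
class RunConfig:
    out_dir: str = "triplethet_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fdr_threshold: float = 0.05
    n_permutations: int = 1000
    min_depth: int = 10
    dispersion_mode: str = "common"
    stages: tuple[str, ...] = STAGES
    focal_parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        for name in ("p_threshold", "lfc_threshold", "fdr_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # dependency order is fixed; requesting a later stage without its
        # prerequisites fails fast by name
        enabled = [s for s in STAGES if s in self.stages]
        for i, s in enumerate(enabled):
            need = STAGES[:STAGES.index(s)]
            missing = [d for d in need if d not in self.stages]
            if missing:
                raise ValueError(
                    f"stage {s!r} requires stage(s) {missing} to be enabled")
        self.stages = tuple(enabled)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        return cls(simulation=SimulationConfig(**sim), **raw)


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root_seq = np.random.SeedSequence(config.seed)
    stage_seeds = {s: spawn_seed(child)
                   for s, child in zip(STAGES, root_seq.spawn(len(STAGES)))}
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "parameters": {
            "p_threshold": config.p_threshold,
            "lfc_threshold": config.lfc_threshold,
            "fdr_threshold": config.fdr_threshold,
            "n_permutations": config.n_permutations,
            "min_depth": config.min_depth,
            "dispersion_mode": config.dispersion_mode,
            "simulation": asdict(config.simulation),
        },
        "stages_run": list(config.stages),
    }
    test_kwargs = dict(alpha=config.p_threshold,
                       lfc_threshold=config.lfc_threshold,
                       dispersion_mode=config.dispersion_mode)

    sim_cfg = SimulationConfig(**{**asdict(config.simulation),
                                  "seed": stage_seeds["simulate"]})
    ds = simulate_triplets(sim_cfg)
    ds.write(out / "dataset")
    design: TripletDesign = sim_cfg.design
    cm = ds.counts
    report["simulate"] = {
        "n_genes": sim_cfg.n_genes,
        "n_samples": cm.counts.shape[1],
        "total_counts": int(cm.counts.to_numpy().sum()),
    }
    if "normalize" not in config.stages:
        _finish(out, report)
        return report

    sf = estimate_size_factors(cm.counts)
    cm.size_factors = sf
    norm = cm.counts / sf
    line_means = average_replicates(norm, cm.samples["line"])
    fpkm = compute_fpkm(cm.counts, ds.gene_lengths, cm.counts.sum(axis=0))
    fpkm.to_csv(out / "fpkm.tsv", sep="\t")
    sf.to_csv(out / "size_factors.tsv", sep="\t")
    rep_corr = {line: round(replicate_correlation(cm, line), 4)
                for line in cm.lines()}
    report["normalize"] = {"replicate_correlation": rep_corr}
    if "deg" not in config.stages:
        _finish(out, report)
        return report

    deg_sets: dict[tuple[str, str], set] = {}
    deg_counts = []

    def deg_between(a: str, b: str) -> set:
        key = (a, b)
        if key not in deg_sets:
            res = nb_wald_test(
                cm.counts_for_line(a), cm.counts_for_line(b),
                sf[cm.samples_for_line(a)], sf[cm.samples_for_line(b)],
                **test_kwargs)
            res.to_csv(out / f"deg_{a}_vs_{b}.tsv", sep="\t")
            deg_sets[key] = set(res.index[res["is_deg"]])
        return deg_sets[key]

    for t in design.triplets:
        for a, b in [(t.parent1, t.parent2), (t.parent1, t.hybrid),
                     (t.parent2, t.hybrid)]:
            n = len(deg_between(a, b))
            deg_counts.append({"comparison": f"{a} vs {b}", "n_deg": n})
    report["deg"] = {"comparisons": deg_counts}
    if "patterns" not in config.stages:
        _finish(out, report)
        return report

    nonadd_sets: dict[str, set] = {}
    pattern_summaries = []
    for t in design.triplets:
        clf = HeterosisPatternClassifier(
            alpha=config.p_threshold, lfc_threshold=config.lfc_threshold,
            dispersion_mode=config.dispersion_mode).fit(cm, t)
        clf.calls_.to_csv(out / f"patterns_{t.hybrid}.tsv", sep="\t")
        nonadd_sets[t.hybrid] = clf.nonadditive_genes_
        summ = clf.range_summary_
        pattern_summaries.append({
            "triplet": f"{t.parent1}-{t.parent2}-{t.hybrid}",
            "n_nonadditive": len(clf.nonadditive_genes_),
            "pct_nonadditive": round_half_up(
                100 * len(clf.nonadditive_genes_) / sim_cfg.n_genes),
            **summ,
        })
    report["patterns"] = {"triplets": pattern_summaries}
    if "ase" not in config.stages:
        _finish(out, report)
        return report

    ase_rng = np.random.SeedSequence(stage_seeds["ase"])
    ase_sets: dict[str, set] = {}
    ase_counts = []
    for t, child in zip(design.triplets, ase_rng.spawn(len(design.triplets))):
        sub = ds.allelic_counts[ds.allelic_counts["hybrid"] == t.hybrid]
        caller = PermutationASECaller(
            n_permutations=config.n_permutations, min_depth=config.min_depth,
            fdr_threshold=config.fdr_threshold,
            random_state=spawn_seed(child)).fit(sub.set_index("gene_id"))
        caller.results_.to_csv(out / f"ase_{t.hybrid}.tsv", sep="\t")
        ase_sets[t.hybrid] = caller.ase_genes_
        overlap = len(caller.ase_genes_ & nonadd_sets[t.hybrid])
        ase_counts.append({"hybrid": t.hybrid,
                           "n_tested": int(caller.results_["tested"].sum()),
                           "n_ase": len(caller.ase_genes_),
                           "ase_and_nonadditive": overlap})
    report["ase"] = {"hybrids": ase_counts}
    if "compare" not in config.stages:
        _finish(out, report)
        return report

    focal = config.focal_parents or design.parents[:2]
    fa, fb = focal
    others = [p for p in design.parents if p not in focal]
    hybrid_of = {frozenset((t.parent1, t.parent2)): t.hybrid
                 for t in design.triplets}
    hybrid_deg = {}
    for c in others:
        ha = hybrid_of[frozenset((fa, c))]
        hb = hybrid_of[frozenset((fb, c))]
        hybrid_deg[f"{ha}|{hb}"] = deg_between(ha, hb)
    additive_candidates = candidate_additive_genes(
        hybrid_deg, deg_between(fa, fb))
    het_a = candidate_heterosis_genes(design, nonadd_sets, fa)
    het_b = candidate_heterosis_genes(design, nonadd_sets, fb)
    shared = shared_heterosis_genes(het_a, het_b)
    for name, s in [("candidate_additive", additive_candidates),
                    (f"candidate_heterosis_{fa}", het_a),
                    (f"candidate_heterosis_{fb}", het_b),
                    ("candidate_heterosis_shared", shared)]:
        (out / f"{name}.txt").write_text("".join(f"{g}\n" for g in sorted(s)))
    report["compare"] = {
        "focal_parents": list(focal),
        "n_candidate_additive": len(additive_candidates),
        f"n_candidate_heterosis_{fa}": len(het_a),
        f"n_candidate_heterosis_{fb}": len(het_b),
        "n_shared_heterosis": len(shared),
    }
    _finish(out, report)
    return report


def _finish(out: Path, report: dict) -> None:
    (out / "run_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
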