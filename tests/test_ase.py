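"""Read assignment rules and the permutation 1:1-deviation caller."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, spearmanr

from triplethet import PermutationASECaller, aggregate_allelic_counts, call_ase
from triplethet.ase import (ReadSnpProfile, SnpSite, assign_read,
                            assign_reads, assign_reads_table)


def _site(obs, a1, a2, pos=0):
    return SnpSite(position=pos, observed=obs, parent1_allele=a1,
                   parent2_allele=a2)


class TestAssignRead:
    def test_all_parent1(self):
        p = ReadSnpProfile("r1", "g1", tuple(
            _site("A", "A", "G", i) for i in range(3)))
        assert assign_read(p) == "parent1"

    def test_no_informative_snp(self):
        p = ReadSnpProfile("r1", "g1", ())
        assert assign_read(p) == "ambiguous"
        # covered sites where parents agree are non-informative, not errors
        p2 = ReadSnpProfile("r1", "g1", (_site("A", "A", "A"),))
        assert assign_read(p2) == "ambiguous"

    def test_conflicting(self):
        sites = (_site("A", "A", "G", 0), _site("A", "A", "G", 1),
                 _site("T", "C", "T", 2))
        p = ReadSnpProfile("r1", "g1", sites)
        assert assign_read(p) == "conflicting"

    def test_mismatching_base_ignored(self):
        # observed base matching neither allele carries no information
        sites = (_site("T", "A", "G", 0), _site("C", "C", "G", 1))
        p = ReadSnpProfile("r1", "g1", sites)
        assert assign_read(p) == "parent1"

    def test_table_agrees_with_per_read_rule(self, rng):
        rows = []
        profiles = []
        for i in range(200):
            n_sites = rng.integers(1, 4)
            sites = []
            for s in range(n_sites):
                a1, a2 = ("A", "G") if rng.random() < 0.9 else ("A", "A")
                obs = a1 if rng.random() < 0.5 else a2
                sites.append(_site(obs, a1, a2, s))
                rows.append({"read_id": f"r{i}", "gene_id": f"g{i % 7}",
                             "observed": obs, "parent1_allele": a1,
                             "parent2_allele": a2})
            profiles.append(ReadSnpProfile(f"r{i}", f"g{i % 7}", tuple(sites)))
        by_profile = assign_reads(profiles).set_index("read_id")["assignment"]
        by_table = assign_reads_table(pd.DataFrame(rows)).set_index(
            "read_id")["assignment"]
        common = by_table.index
        assert (by_profile[common] == by_table[common]).all()


class TestAggregate:
    def test_example(self):
        a = pd.DataFrame({
            "gene_id": ["g1"] * 18,
            "assignment": ["parent1"] * 10 + ["parent2"] * 5
            + ["ambiguous"] * 3,
        })
        out = aggregate_allelic_counts(a)
        assert (out.loc["g1", "n1"], out.loc["g1", "n2"]) == (10, 5)

    def test_empty_gene(self):
        a = pd.DataFrame({"gene_id": ["g1"], "assignment": ["parent1"]})
        out = aggregate_allelic_counts(a, genes=["g1", "g2"])
        assert (out.loc["g2"] == 0).all()

    def test_matches_brute_force(self, rng):
        a = pd.DataFrame({
            "gene_id": rng.choice([f"g{i}" for i in range(5)], 300),
            "assignment": rng.choice(
                ["parent1", "parent2", "ambiguous", "conflicting"], 300),
        })
        out = aggregate_allelic_counts(a)
        for g, sub in a.groupby("gene_id"):
            assert out.loc[g, "n1"] == (sub["assignment"] == "parent1").sum()
            assert out.loc[g, "n2"] == (sub["assignment"] == "parent2").sum()


def _table(pairs):
    return pd.DataFrame(pairs, columns=["n1", "n2"],
                        index=[f"g{i}" for i in range(len(pairs))])


class TestPermutationCaller:
    def test_perfect_balance_p_one(self):
        res = call_ase(_table([(50, 50), (40, 60), (55, 45)]), seed=1)
        assert res.loc["g0", "perm_p"] == 1.0
        assert not res.loc["g0", "is_ase"]

    def test_total_imbalance_minimum_p(self):
        """(100, 0) reaches the smallest attainable p = 1/(B+1): the
        binomial tail at distance n/2 is ~2^-99, negligible against 1/B."""
        pairs = [(100, 0)] + [(50 + d, 50 - d) for d in range(-5, 6)]
        res = call_ase(_table(pairs), n_permutations=1000, seed=2)
        assert res.loc["g0", "perm_p"] == pytest.approx(1 / 1001)
        assert res.loc["g0", "is_ase"]
        assert res.loc["g0", "biased_parent"] == "parent1"

    def test_p_on_permutation_grid(self, rng):
        pairs = [(int(a), int(b)) for a, b in
                 rng.integers(10, 200, size=(40, 2))]
        res = call_ase(_table(pairs), n_permutations=250, seed=3)
        tested = res[res["tested"]]
        k = tested["perm_p"] * 251
        np.testing.assert_allclose(k, np.rint(k), atol=1e-9)
        assert (tested["perm_p"] >= 1 / 251).all()

    def test_swap_symmetry(self, rng):
        pairs = rng.integers(5, 300, size=(60, 2))
        a = call_ase(_table([tuple(p) for p in pairs]), seed=7)
        b = call_ase(_table([(p[1], p[0]) for p in pairs]), seed=7)
        tested = a["tested"] & b["tested"]
        np.testing.assert_array_equal(a.loc[tested, "perm_p"],
                                      b.loc[tested, "perm_p"])

    def test_min_depth_marks_untested(self):
        res = call_ase(_table([(3, 2), (80, 40), (90, 30)]), min_depth=10,
                       seed=4)
        assert not res.loc["g0", "tested"]
        assert np.isnan(res.loc["g0", "perm_p"])  # never silently p = 1

    def test_depth_below_min_everywhere(self):
        res = call_ase(_table([(3, 2), (1, 4), (2, 2)]), min_depth=100,
                       seed=4)
        assert not res["tested"].any()
        assert not res["is_ase"].any()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PermutationASECaller(n_permutations=0).fit(_table([(5, 5)]))
        with pytest.raises(ValueError):
            PermutationASECaller(min_depth=0).fit(_table([(5, 5)]))
        with pytest.raises(ValueError):
            call_ase(_table([(-1, 5)]))

    def test_reproducible_under_seed(self, rng):
        pairs = [tuple(p) for p in rng.integers(20, 200, size=(30, 2))]
        a = call_ase(_table(pairs), seed=11)
        b = call_ase(_table(pairs), seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_bh_q_monotone_in_p(self, rng):
        pairs = [tuple(p) for p in rng.integers(20, 400, size=(80, 2))]
        res = call_ase(_table(pairs), seed=13)
        t = res[res["tested"]].sort_values("perm_p")
        assert (t["fdr_q"].diff().dropna() >= -1e-12).all()

    def test_agrees_with_exact_binomial(self, rng):
        """The permutation scheme is a Monte-Carlo binomial test: its p
        ranks match the exact two-sided binomial p."""
        n = 100
        n1 = rng.binomial(n, 0.5, 300)
        caller = PermutationASECaller(n_permutations=1000, random_state=17,
                                      normalize=False)
        res = caller.fit(_table(list(zip(n1, n - n1)))).results_
        exact = [binomtest(int(k), n, 0.5).pvalue for k in res["n1"]]
        rho = spearmanr(res["perm_p"], exact).statistic
        assert rho > 0.99

    def test_power_monotone_in_effect(self, rng):
        n = 100
        out = {}
        for bias in (0.6, 0.9):
            n1 = rng.binomial(n, bias, 300)
            caller = PermutationASECaller(random_state=19, normalize=False)
            res = caller.fit(_table(list(zip(n1, n - n1)))).results_
            out[bias] = res["is_ase"].mean()
        assert out[0.9] > out[0.6]
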