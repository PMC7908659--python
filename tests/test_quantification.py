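"""QC arithmetic, size factors, FPKM, replicate handling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triplethet import (SizeFactorNormalizer, average_replicates,
                        compute_fpkm, estimate_size_factors, qc_table,
                        replicate_correlation, summarize_library_qc)
from triplethet.io import load_library_read_stats

from conftest import toy_count_matrix


class TestLibraryQC:
    @pytest.mark.parametrize(
        "raw,clean,mapped,retention,mapped_rate",
        [
            (13_871_140, 13_443_019, 11_622_834, 96.91, 86.46),
            (14_658_208, 13_170_436, 10_408_596, 89.85, 79.03),
            (1_000, 1_000, 1_000, 100.00, 100.00),
        ],
    )
    def test_rates(self, raw, clean, mapped, retention, mapped_rate):
        qc = summarize_library_qc(raw, clean, mapped)
        assert qc.retention_rate == retention
        assert qc.mapped_rate == mapped_rate

    def test_zero_reads_error(self):
        with pytest.raises(ZeroDivisionError):
            summarize_library_qc(0, 0, 0)

    def test_ordering_violation(self):
        with pytest.raises(ValueError):
            summarize_library_qc(100, 200, 50)

    @settings(max_examples=50, deadline=None)
    @given(raw=st.integers(1, 10**8), data=st.data())
    def test_rates_bounded(self, raw, data):
        clean = data.draw(st.integers(0, raw))
        mapped = data.draw(st.integers(0, clean))
        if clean == 0:
            return
        qc = summarize_library_qc(raw, clean, mapped)
        assert 0 <= qc.mapped_rate <= 100
        assert 0 <= qc.retention_rate <= 100

    def test_full_study_table(self):
        """Every printed per-library rate is reproduced from the counts."""
        stats = load_library_read_stats()
        table = qc_table(stats)
        body = table.iloc[:-1]
        np.testing.assert_array_equal(
            body["retention_rate"].to_numpy(),
            stats["retention_rate_pct"].to_numpy())
        np.testing.assert_array_equal(
            body["mapped_rate"].to_numpy(), stats["mapped_rate_pct"].to_numpy())
        total = table.iloc[-1]
        assert total["retention_rate"] == 96.48
        assert total["mapped_rate"] == 85.47


class TestSizeFactors:
    def test_identical_samples(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        np.testing.assert_allclose(estimate_size_factors(df), 1.0)

    def test_doubled_sample(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [20, 40, 10]})
        sf = estimate_size_factors(df)
        np.testing.assert_allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_matches_brute_force(self, rng):
        counts = pd.DataFrame(rng.negative_binomial(5, 0.05, size=(200, 5)))
        sf = estimate_size_factors(counts)
        # independent recomputation, elementwise loops
        arr = counts.to_numpy(float)
        keep = [i for i in range(arr.shape[0]) if all(arr[i] > 0)]
        expected = []
        for j in range(arr.shape[1]):
            ratios = []
            for i in keep:
                ref = np.exp(np.mean([np.log(v) for v in arr[i]]))
                ratios.append(arr[i, j] / ref)
            expected.append(np.median(ratios))
        np.testing.assert_allclose(sf.to_numpy(), expected, atol=1e-12)

    def test_no_common_positive_gene_errors(self):
        df = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            estimate_size_factors(df)

    @settings(max_examples=25, deadline=None)
    @given(c=st.floats(0.25, 4.0), seed=st.integers(0, 100))
    def test_scale_equivariance(self, c, seed):
        """Scaling one of m samples by c rescales its factor by
        c^((m-1)/m) and every other factor by c^(-1/m), exactly: the
        geometric-mean reference absorbs c^(1/m), so factor *ratios* are
        equivariant (consistent with the (1/sqrt(2), sqrt(2)) doubling
        case)."""
        r = np.random.default_rng(seed)
        m = 4
        counts = pd.DataFrame(r.poisson(50, size=(100, m)) + 1)
        sf = estimate_size_factors(counts)
        scaled = counts.astype(float).copy()
        scaled[0] = scaled[0] * c
        sf2 = estimate_size_factors(scaled)
        np.testing.assert_allclose(sf2[0], sf[0] * c ** ((m - 1) / m),
                                   rtol=1e-9)
        for j in range(1, m):
            np.testing.assert_allclose(sf2[j], sf[j] * c ** (-1 / m),
                                       rtol=1e-9)
        np.testing.assert_allclose((sf2[0] / sf2[1]) / (sf[0] / sf[1]), c,
                                   rtol=1e-9)

    def test_normalizer_estimator(self, rng):
        counts = pd.DataFrame(rng.poisson(40, size=(80, 3)) + 1,
                              columns=list("abc"))
        norm = SizeFactorNormalizer()
        out = norm.fit_transform(counts)
        np.testing.assert_allclose(
            out.to_numpy(), (counts / norm.size_factors_).to_numpy())
        assert norm.get_params() == {}
        with pytest.raises(ValueError):
            norm.transform(counts.rename(columns={"a": "zzz"}))


class TestFpkm:
    def test_unit_case(self):
        out = compute_fpkm(pd.DataFrame({"s": [10, 0]}, index=["g1", "g2"]),
                           {"g1": 1000, "g2": 500}, {"s": 1_000_000})
        assert out.loc["g1", "s"] == pytest.approx(10.0)
        assert out.loc["g2", "s"] == 0.0

    def test_matches_formula(self, rng):
        counts = pd.DataFrame(rng.poisson(30, size=(50, 4)))
        lengths = pd.Series(rng.integers(500, 5000, 50), index=counts.index)
        totals = pd.Series(rng.integers(10**6, 10**7, 4), index=counts.columns)
        out = compute_fpkm(counts, lengths, totals)
        for i in range(0, 50, 7):
            for j in range(4):
                expected = counts.iat[i, j] * 1e9 / (
                    lengths.iloc[i] * totals.iloc[j])
                assert out.iat[i, j] == pytest.approx(expected, abs=1e-12)

    def test_split_gene_invariance(self):
        """Splitting a gene's counts across two equal-length genes
        preserves the FPKM total."""
        one = compute_fpkm(pd.DataFrame({"s": [30]}, index=["g"]),
                           {"g": 2000}, {"s": 10**6})
        two = compute_fpkm(pd.DataFrame({"s": [12, 18]}, index=["g1", "g2"]),
                           {"g1": 2000, "g2": 2000}, {"s": 10**6})
        assert two["s"].sum() == pytest.approx(one.loc["g", "s"])

    def test_zero_length_error(self):
        with pytest.raises(ValueError):
            compute_fpkm(pd.DataFrame({"s": [1]}, index=["g"]), {"g": 0},
                         {"s": 100})


class TestReplicates:
    def test_identical_replicates_correlation_one(self, rng):
        cm = toy_count_matrix(rng, lines=("A",))
        cm.counts["A-2"] = cm.counts["A-1"]
        cm.size_factors = pd.Series(1.0, index=cm.counts.columns)
        assert replicate_correlation(cm, "A") == pytest.approx(1.0)

    def test_scaled_replicate_correlation_one(self, rng):
        """Exact depth scaling is removed by normalization."""
        cm = toy_count_matrix(rng, lines=("A",))
        cm.counts["A-2"] = cm.counts["A-1"] * 2
        assert replicate_correlation(cm, "A") == pytest.approx(1.0, abs=1e-9)

    def test_simulated_replicates_agree(self, null_dataset):
        for line in ("T121", "T121xT126"):
            assert replicate_correlation(null_dataset.counts, line) > 0.9

    def test_constant_vector_error(self, rng):
        cm = toy_count_matrix(rng, lines=("A",), n_genes=10)
        cm.counts["A-1"] = 5
        cm.size_factors = pd.Series(1.0, index=cm.counts.columns)
        with pytest.raises(ValueError, match="constant"):
            replicate_correlation(cm, "A")

    def test_average_replicates(self, rng):
        values = pd.DataFrame({"A-1": [2.0, 1.0], "A-2": [4.0, 1.0],
                               "B-1": [6.0, 0.0], "B-2": [8.0, 2.0]})
        lines = {"A-1": "A", "A-2": "A", "B-1": "B", "B-2": "B"}
        out = average_replicates(values, lines)
        np.testing.assert_allclose(out["A"], [3.0, 1.0])
        np.testing.assert_allclose(out["B"], [7.0, 1.0])
        with pytest.raises(KeyError):
            average_replicates(values, lines, lines=["A", "missing"])

    def test_average_matches_brute_force(self, rng):
        values = pd.DataFrame(rng.random((20, 6)),
                              columns=[f"L{i//3}-{i%3}" for i in range(6)])
        lines = {c: c.split("-")[0] for c in values.columns}
        out = average_replicates(values, lines)
        for line in ("L0", "L1"):
            cols = [c for c in values.columns if lines[c] == line]
            np.testing.assert_allclose(
                out[line], values[cols].sum(axis=1) / len(cols))
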