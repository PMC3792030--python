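import math
import statistics

import numpy as np
import pandas as pd
import pytest

from decayscan import SimulationConfig, simulate_dataset
from decayscan.diffexpr import (
    bh_adjust,
    dispersions_for_table,
    nb_exact_pvalue,
    nb_test,
    size_factors,
)
from decayscan.io import CountsTable


def log_median(ratios):
    """Median of positive ratios taken on the log scale.

    For an odd count this is the middle ratio; for an even count the
    geometric midpoint of the two middle ratios (the median-of-ratios
    convention medians the log ratios).
    """
    ordered = sorted(ratios)
    n = len(ordered)
    if n % 2:
        return ordered[n // 2]
    return math.sqrt(ordered[n // 2 - 1] * ordered[n // 2])


def brute_force_size_factors(matrix):
    """Median-of-ratios by explicit enumeration (independent oracle)."""
    n_genes = len(matrix)
    n_samples = len(matrix[0])
    geomeans = []
    for g in range(n_genes):
        row = [matrix[g][j] for j in range(n_samples)]
        if all(v > 0 for v in row):
            geomeans.append(math.exp(sum(math.log(v) for v in row) / n_samples))
        else:
            geomeans.append(None)
    factors = []
    for j in range(n_samples):
        ratios = [
            matrix[g][j] / geomeans[g] for g in range(n_genes) if geomeans[g] is not None
        ]
        factors.append(log_median(ratios))
    return factors


def brute_force_bh(pvalues):
    """Step-up adjustment written as the textbook procedure."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        adjusted[i] = running
    return adjusted


def make_table(values, conditions, phases, sample_ids=None):
    values = np.asarray(values)
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    counts = pd.DataFrame(
        values,
        index=pd.Index([f"g{i}" for i in range(values.shape[0])], name="transcript_id"),
        columns=sample_ids,
    )
    samples = pd.DataFrame(
        {
            "condition": conditions,
            "phase": phases,
            "replicate": list(range(1, len(sample_ids) + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return CountsTable(counts, samples)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame({"a": [3, 10, 7], "b": [3, 10, 7]})
        np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])

    def test_doubled_column_doubles_factor(self):
        counts = pd.DataFrame({"a": [3, 10, 7, 2], "b": [6, 20, 14, 4]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_on_toy_matrix(self):
        matrix = [[1, 2, 3], [4, 8, 4], [10, 5, 20], [7, 7, 7], [0, 3, 9]]
        got = size_factors(pd.DataFrame(matrix, columns=list("abc")))
        np.testing.assert_allclose(got, brute_force_size_factors(matrix), rtol=1e-12)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            matrix = rng.poisson(30, size=(int(rng.integers(4, 20)), int(rng.integers(2, 6))))
            matrix[rng.random(matrix.shape) < 0.1] = 0
            if not (matrix > 0).all(axis=1).any():
                matrix[0, :] = 5
            got = size_factors(pd.DataFrame(matrix))
            np.testing.assert_allclose(got, brute_force_size_factors(matrix), rtol=1e-12)

    def test_matches_independent_deseq_implementation(self, rng):
        pydeseq2_prep = pytest.importorskip("pydeseq2.preprocessing")
        matrix = rng.poisson(50, size=(60, 4)).astype(float)
        _, sf = pydeseq2_prep.deseq2_norm(pd.DataFrame(matrix).T)
        ours = size_factors(pd.DataFrame(matrix))
        np.testing.assert_allclose(ours, np.asarray(sf), rtol=1e-9)

    def test_all_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"a": [1, 2], "b": [0, 0]}))


class TestBHAdjust:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.03])), [0.03])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), np.full(7, 0.2))

    def test_hand_worked_example(self):
        got = bh_adjust(np.array([0.01, 0.02, 0.03, 0.8]))
        np.testing.assert_allclose(got, [0.04, 0.04, 0.04, 0.8], rtol=1e-12)

    def test_matches_brute_force_on_random_fixtures(self, rng):
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(list(p)), rtol=1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(200)
        _, expected, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.1, 1.2]))
        with pytest.raises(ValueError):
            bh_adjust(np.array([np.nan]))

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(500)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestNbExactPvalue:
    def test_zero_total_is_null(self):
        assert nb_exact_pvalue(0, 0, np.ones(2), np.ones(2), 0.05) == 1.0

    def test_balanced_split_is_least_extreme(self):
        p = nb_exact_pvalue(500, 500, np.ones(2), np.ones(2), 0.05)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_extreme_split_is_significant(self):
        p = nb_exact_pvalue(50, 950, np.ones(2), np.ones(2), 0.05)
        assert p < 1e-3

    def test_symmetry_in_conditions(self):
        a = nb_exact_pvalue(100, 300, np.ones(2), np.ones(2), 0.1)
        b = nb_exact_pvalue(300, 100, np.ones(2), np.ones(2), 0.1)
        assert a == pytest.approx(b, rel=1e-9)


class TestNbTest:
    def test_identical_conditions_give_zero_log2fc(self):
        values = np.tile(np.array([[40], [400], [4000]]), (1, 4))
        table = make_table(values, ["WT", "WT", "mutant", "mutant"], ["log"] * 4)
        result = nb_test(table, "log")
        assert (result["log2fc"] == 0.0).all()
        assert (result["padj"] >= result["pvalue"] - 1e-15).all()

    def test_sample_order_is_irrelevant(self, rng):
        values = rng.poisson(100, size=(30, 4))
        conditions = ["WT", "mutant", "WT", "mutant"]
        table = make_table(values, conditions, ["log"] * 4)
        base = nb_test(table, "log")
        perm = [2, 0, 3, 1]
        table2 = make_table(values[:, perm], [conditions[j] for j in perm], ["log"] * 4,
                            sample_ids=[f"s{j}" for j in perm])
        shuffled = nb_test(table2, "log")
        pd.testing.assert_frame_equal(base, shuffled)

    def test_doubling_a_sample_doubles_its_size_factor_only(self, rng):
        values = rng.poisson(300, size=(50, 4)) + 1
        conditions = ["WT", "WT", "mutant", "mutant"]
        table = make_table(values, conditions, ["log"] * 4)
        doubled = values.copy()
        doubled[:, 0] *= 2
        table2 = make_table(doubled, conditions, ["log"] * 4)
        sf1 = size_factors(table.counts)
        sf2 = size_factors(table2.counts)
        # size factors are defined up to a common scale: the doubled
        # sample's factor doubles relative to every other sample
        ratio = (sf2.iloc[0] / sf2.iloc[1]) / (sf1.iloc[0] / sf1.iloc[1])
        assert ratio == pytest.approx(2.0, rel=1e-9)
        r1, r2 = nb_test(table, "log"), nb_test(table2, "log")
        high = r1["base_mean"] > 100
        np.testing.assert_allclose(
            r1.loc[high, "log2fc"], r2.loc[high, "log2fc"], atol=1e-3
        )

    def test_all_zero_transcript_reported_na(self):
        values = np.array([[10, 12, 9, 11], [0, 0, 0, 0]])
        table = make_table(values, ["WT", "WT", "mutant", "mutant"], ["log"] * 4)
        result = nb_test(table, "log").set_index("transcript_id")
        assert np.isnan(result.loc["g1", "pvalue"]) and np.isnan(result.loc["g1", "padj"])
        assert np.isfinite(result.loc["g0", "pvalue"])

    def test_single_replicate_condition_rejected(self):
        values = np.array([[10, 9, 11]])
        table = make_table(values, ["WT", "mutant", "mutant"], ["log"] * 3)
        with pytest.raises(ValueError, match="replicate"):
            nb_test(table, "log")

    def test_power_is_monotone_in_padj_threshold(self):
        config = SimulationConfig(
            n_transcripts=300, mean_depth=600, target_log2fc=2.0,
            decay_depth=0.0, phases=("log",), seed=77,
        )
        ds = simulate_dataset(config)
        result = nb_test(ds.counts, "log").set_index("transcript_id")
        targets = ds.truth.index[ds.truth["is_target"]]
        padj = result.loc[targets, "padj"]
        sens_10 = float((padj < 0.10).mean())
        sens_01 = float((padj < 0.01).mean())
        assert sens_10 >= sens_01
        assert sens_10 > 0.8  # strong shift at this depth should be detected

    def test_dispersion_estimates_recover_simulated_alpha(self):
        config = SimulationConfig(
            n_transcripts=400, mean_depth=800, nb_dispersion=0.08,
            decay_depth=0.0, target_log2fc=0.0, seed=31,
        )
        ds = simulate_dataset(config)
        alpha = dispersions_for_table(ds.counts)
        assert np.nanmedian(alpha) == pytest.approx(0.08, rel=0.35)
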