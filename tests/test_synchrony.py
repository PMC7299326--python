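"""Dyad enumeration, distances, per-gene synchrony calls, coclustering."""

from math import comb

import numpy as np
import pandas as pd
import pytest

from fightsync import (ExpressionMatrix, GeneSet, assign_sync_pairs,
                       enumerate_sample_pairs, gene_pair_distances,
                       gene_sync_test, group_sync_test, pair_coclustering,
                       sample_correlations, simulate_design, sync_baseline,
                       sync_pipeline, top_variable_genes)
from fightsync.synchrony import GeneDistanceTable, default_epsilon


def _design(n_pairs):
    return simulate_design(1, n_pairs)


class TestEnumeratePairs:
    def test_study_scale_counts(self):
        pt = enumerate_sample_pairs(_design(5), "D60")
        assert len(pt.table) == 45
        assert pt.n_paired == 5
        assert (~pt.table["is_paired"]).sum() == 40
        # every sample participates in n-1 dyads
        appearances = pd.concat([pt.table["sample_1"], pt.table["sample_2"]])
        assert (appearances.value_counts() == 9).all()

    def test_two_pairs(self):
        pt = enumerate_sample_pairs(_design(2), "D20")
        assert len(pt.table) == 6
        assert pt.n_paired == 2

    def test_single_pair(self):
        pt = enumerate_sample_pairs(_design(1), "D60")
        assert len(pt.table) == 1
        assert bool(pt.table["is_paired"].iloc[0])

    def test_absent_group(self):
        design = _design(2)
        with pytest.raises(ValueError, match="absent"):
            enumerate_sample_pairs(design[design["group"] != "D20"], "D20")


def _expr(frame, scale="linear"):
    return ExpressionMatrix(frame, scale=scale)


class TestSampleCorrelations:
    def test_copy_and_reversal(self):
        design = _design(1)
        pt = enumerate_sample_pairs(design, "D60")
        s1, s2 = pt.table.loc[0, ["sample_1", "sample_2"]]
        frame = pd.DataFrame({s1: [1.0, 2.0, 3.0], s2: [1.0, 2.0, 3.0]})
        r = sample_correlations(_expr(frame, "log2"), pt)["r"].iloc[0]
        assert r == pytest.approx(1.0)
        frame[s2] = [3.0, 2.0, 1.0]
        r = sample_correlations(_expr(frame, "log2"), pt)["r"].iloc[0]
        assert r == pytest.approx(-1.0)

    def test_zero_variance_sample_named(self):
        design = _design(1)
        pt = enumerate_sample_pairs(design, "D60")
        s1, s2 = pt.table.loc[0, ["sample_1", "sample_2"]]
        frame = pd.DataFrame({s1: [1.0, 2.0, 3.0], s2: [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match=s2):
            sample_correlations(_expr(frame, "log2"), pt)

    def test_paired_exceed_unpaired_in_strong_regime(self, log_tmm, design):
        pt = enumerate_sample_pairs(design, "D60")
        corr = sample_correlations(log_tmm, pt)
        assert corr.loc[corr["is_paired"], "r"].mean() > \
            corr.loc[~corr["is_paired"], "r"].mean()
        assert group_sync_test(corr) < 0.01


class TestDistances:
    def _table(self, frame, pairing, eps=1e-9):
        return gene_pair_distances(_expr(frame), pairing, epsilon=eps)

    def test_known_values_and_symmetry(self):
        pt = enumerate_sample_pairs(_design(1), "D60")
        s1, s2 = pt.table.loc[0, ["sample_1", "sample_2"]]
        frame = pd.DataFrame({s1: [100.0, 7.0], s2: [10.0, 7.0]})
        d = self._table(frame, pt).distances
        assert d.iloc[0, 0] == pytest.approx(1.0, abs=1e-6)
        assert d.iloc[1, 0] == pytest.approx(0.0)
        swapped = self._table(frame[[s2, s1]].set_axis([s1, s2], axis=1), pt)
        assert np.allclose(d, swapped.distances)

    def test_log_scale_rejected(self, log_tmm, design):
        pt = enumerate_sample_pairs(design, "D60")
        with pytest.raises(ValueError, match="linear"):
            gene_pair_distances(log_tmm, pt)

    def test_default_epsilon_is_half_min_positive(self):
        frame = pd.DataFrame({"a": [0.0, 4.0], "b": [2.0, 8.0]})
        assert default_epsilon(frame) == 1.0


def _distance_table(n_genes, paired_vals, unpaired_vals, seed=0):
    """Distance table over the 45 dyads of a 5-pair group."""
    pt = enumerate_sample_pairs(_design(5), "D60")
    rng = np.random.default_rng(seed)
    paired = np.asarray(paired_vals, float)
    unpaired = np.asarray(unpaired_vals, float)
    rows = np.empty((n_genes, 45))
    is_p = pt.table["is_paired"].to_numpy()
    rows[:, is_p] = paired
    rows[:, ~is_p] = unpaired
    dist = pd.DataFrame(rows, index=[f"g{i}" for i in range(n_genes)],
                        columns=pt.dyad_labels)
    return GeneDistanceTable(dist, pt, 1e-6)


class TestGeneSyncTest:
    def test_extreme_gene_synchronized(self):
        table = _distance_table(1, np.zeros(5), np.linspace(1, 2, 40))
        out = gene_sync_test(table, mode="exact_enum")
        assert out["p_value"].iloc[0] == pytest.approx(1 / comb(45, 5))
        assert bool(out["is_synchronized"].iloc[0])

    def test_flat_gene_not_synchronized(self):
        table = _distance_table(1, np.full(5, 0.3), np.full(40, 0.3))
        out = gene_sync_test(table)
        assert out["p_value"].iloc[0] == 1.0
        assert not bool(out["is_synchronized"].iloc[0])

    def test_invariant_to_common_rescaling(self):
        rng = np.random.default_rng(3)
        t1 = _distance_table(5, rng.exponential(1, 5), rng.exponential(1, 40))
        t2 = GeneDistanceTable(t1.distances * 7.5, t1.pairing, t1.epsilon)
        p1 = gene_sync_test(t1)["p_value"]
        p2 = gene_sync_test(t2)["p_value"]
        assert np.allclose(p1, p2)


class TestBaselineAndAssignment:
    def test_percentile_convention(self):
        t = _distance_table(1, np.zeros(5), np.arange(1, 41))
        assert sync_baseline(t).iloc[0] == pytest.approx(10.75)

    def test_constant_and_small_sets(self):
        t = _distance_table(1, np.zeros(5), np.full(40, 0.77))
        assert sync_baseline(t).iloc[0] == pytest.approx(0.77)
        pt = enumerate_sample_pairs(_design(2), "D60")  # only 4 unpaired
        vals = pd.DataFrame([[0, 0, 0.0, 0, 0, 4.0]],
                            columns=pt.dyad_labels)
        vals.loc[0, ~pt.table["is_paired"].to_numpy()] = [0, 0, 0, 4.0]
        vals.loc[0, pt.table["is_paired"].to_numpy()] = 0.0
        table = GeneDistanceTable(vals, pt, 1e-6)
        assert sync_baseline(table).iloc[0] == pytest.approx(0.0)

    def test_strict_inequality_at_boundary(self):
        t = _distance_table(2, np.full(5, 0.5), np.linspace(0.4, 2, 40))
        flags = pd.Series([True, True], index=t.distances.index)
        base = pd.Series([0.5, 0.6], index=t.distances.index)
        res = assign_sync_pairs(t, flags, base)
        # D == B in gene 0: no pair counts; D < B in gene 1: all five do
        assert res.table["n_pairs_synchronized"].tolist() == [0, 5]

    def test_nonsynchronized_genes_get_no_pairs(self):
        t = _distance_table(1, np.zeros(5), np.ones(40))
        flags = pd.Series([False], index=t.distances.index)
        base = pd.Series([0.9], index=t.distances.index)
        res = assign_sync_pairs(t, flags, base)
        assert res.table["n_pairs_synchronized"].iloc[0] == 0
        assert res.tally == {k: 0 for k in range(1, 6)}


class TestTopVariableGenes:
    def test_study_scale_fractions(self):
        rng = np.random.default_rng(0)
        n = 23306
        frame = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                             index=[f"g{i:05d}" for i in range(n)])
        expr = ExpressionMatrix(frame, scale="log2")
        assert len(top_variable_genes(expr, 0.5)) == 11653
        assert len(top_variable_genes(expr, 0.1)) == 2330
        assert len(top_variable_genes(expr, 1.0)) == n

    def test_deterministic_tie_break(self):
        frame = pd.DataFrame({"a": [0.0, 0.0, 1.0], "b": [2.0, 2.0, 5.0]},
                             index=["gb", "ga", "gc"])
        expr = ExpressionMatrix(frame, scale="log2")
        assert set(top_variable_genes(expr, 2 / 3).genes) == {"gc", "ga"}

    def test_fraction_range(self, log_tmm):
        with pytest.raises(ValueError):
            top_variable_genes(log_tmm, 0.0)


class TestCoclustering:
    def test_perfect_pairs_score_one(self):
        design = _design(2)
        samples = design.loc[design["group"] == "D60", "sample_id"].tolist()
        rng = np.random.default_rng(1)
        profiles = {}
        for pair in (0, 1):
            shared = rng.normal(size=50)
            for k in (0, 1):
                profiles[samples[2 * pair + k]] = shared + rng.normal(0, 0.01, 50)
        # baseline samples present but unused by the group clustering
        frame = pd.DataFrame(profiles)
        expr = ExpressionMatrix(frame, scale="log2")
        score, Z, leaves = pair_coclustering(expr, design, "D60")
        assert score == 1.0

    def test_d60_regime_clusters_pairs(self, log_tmm, design):
        score, _, _ = pair_coclustering(log_tmm, design, "D60")
        assert score == 1.0


class TestSyncPipeline:
    def test_empty_deg_set(self, sim_data, design):
        counts, _, _ = sim_data
        out = sync_pipeline(counts, design, "D60", GeneSet("none", frozenset()))
        assert out.n_deg == 0
        assert out.n_synchronized == 0
        assert all(v == 0 for v in out.tally.values())

    def test_internal_consistency(self, sim_data, design):
        counts, truth, _ = sim_data
        genes = truth.table.index[truth.table["is_responsive"]][:80]
        out = sync_pipeline(counts, design, "D60",
                            GeneSet("resp", frozenset(genes)), seed=0)
        t = out.result.table
        assert out.n_deg == len(t)
        assert out.n_synchronized == t["is_synchronized"].sum()
        assert sum(out.tally.values()) <= out.n_synchronized
        flag_cols = [c for c in t.columns if c.startswith("sync_in_")]
        assert (t[flag_cols].sum(axis=1) == t["n_pairs_synchronized"]).all()
        assert ((t.loc[~t["is_synchronized"], "n_pairs_synchronized"]) == 0).all()
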