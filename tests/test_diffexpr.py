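"""Differential-expression calls, BH-FDR, Venn/overlap set statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from fightsync import (DEResult, ExpressionMatrix, GeneSet, bh_fdr, de_test,
                       overlap_hypergeometric, projection_categories,
                       select_degs, venn_partition)
from fightsync.normalization import log_transform


def _log_expr(rows, samples):
    df = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))],
                      columns=samples)
    return ExpressionMatrix(df, scale="log2")


def bh_oracle(p):
    """Literal step-up: p_(i) * m / i, running minimum from the largest."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestBhFdr:
    def test_hand_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert bh_fdr([0.123]) == pytest.approx([0.123])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    def test_matches_bruteforce_stepup(self, pvals):
        assert np.allclose(bh_fdr(pvals), bh_oracle(pvals), atol=1e-12)


class TestDeTest:
    def test_logfc_and_constant_convention(self):
        a = ["a1", "a2", "a3"]
        b = ["b1", "b2", "b3"]
        rows = [[8, 8.1, 7.9, 10, 10.1, 9.9],   # means 8 vs 10 -> lfc 2
                [5, 5, 5, 5, 5, 5]]              # constant -> p 1, flagged
        res = de_test(_log_expr(rows, a + b), a, b)
        assert res.table.loc["g0", "log2_fc"] == pytest.approx(2.0, abs=1e-9)
        assert res.table.loc["g1", "p_value"] == 1.0
        assert bool(res.table.loc["g1", "is_constant"])
        assert res.table.loc["g0", "direction"] == "up"

    def test_group_overlap_rejected(self):
        expr = _log_expr([[1, 2, 3, 4]], ["s1", "s2", "s3", "s4"])
        with pytest.raises(ValueError, match="overlap"):
            de_test(expr, ["s1", "s2"], ["s2", "s3"])

    def test_requires_log_scale(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2, 3, 4]],
                                             columns=list("abcd")))
        with pytest.raises(ValueError, match="log2"):
            de_test(expr, ["a", "b"], ["c", "d"])

    def test_ranking_enriches_truth(self, design):
        # 10% responders with lfc 3 at phi = 0.1: p-ranking separates truth
        from fightsync import SimParams, normalize, simulate_counts
        params = SimParams(n_genes=1000, dispersion=0.1, frac_responsive=0.1,
                           frac_synchronized_of_responsive=0.0,
                           lfc_mu=3.0, lfc_sigma=0.0, sigma_fish=0.0, seed=21)
        counts, truth = simulate_counts(design, params)
        _, _, tmm = normalize(counts)
        base = design.loc[design["group"] == "B", "sample_id"].tolist()
        d60 = design.loc[design["group"] == "D60", "sample_id"].tolist()
        res = de_test(log_transform(tmm), base, d60)
        tab = res.table.join(truth.table["is_responsive"])
        ranks = tab["p_value"].rank()
        pos = ranks[tab["is_responsive"]]
        neg = ranks[~tab["is_responsive"]]
        auroc = 1.0 - (pos.sum() - len(pos) * (len(pos) + 1) / 2) / (len(pos) * len(neg))
        assert auroc > 0.9


class TestSelectDegs:
    @pytest.fixture()
    def toy_de(self):
        table = pd.DataFrame({
            "log2_fc": [2.5, 0.5, -3.0, 2.2, 1.0],
            "p_value": [1e-4, 1e-3, 1e-4, 0.2, 1e-5],
            "fdr": [0.04, 0.04, 0.01, 0.5, 0.001],
            "direction": ["up", "up", "down", "up", "up"],
            "is_constant": [False] * 5,
        }, index=[f"g{i}" for i in range(5)])
        return DEResult(table)

    def test_profiles(self, toy_de):
        char = select_degs(toy_de, "characterization")
        sync = select_degs(toy_de, "sync_input")
        assert char.genes == {"g0", "g2"}
        assert sync.genes == {"g0", "g1", "g4"}
        assert char.provenance["fdr_max"] == 0.05

    def test_custom_thresholds(self, toy_de):
        custom = select_degs(toy_de, "custom", fdr_max=0.05,
                             min_abs_lfc=1.5, direction="up")
        assert custom.genes == {"g0"}

    def test_unknown_profile(self, toy_de):
        with pytest.raises(ValueError, match="profile"):
            select_degs(toy_de, "everything")


class TestSetStatistics:
    def test_venn_study_scale_numbers(self):
        universe = [f"g{i}" for i in range(1100)]
        both = set(universe[:295])
        a = GeneSet("d20", frozenset(both | set(universe[295:518])))
        b = GeneSet("d60", frozenset(both | set(universe[518:518 + 564])))
        v = venn_partition(a, b)
        assert (v.a_only, v.b_only, v.both) == (223, 564, 295)
        assert v.union == 1082

    def test_venn_degenerate(self):
        a = GeneSet("a", frozenset("xyz"))
        assert venn_partition(a, a) == (0, 0, 3)
        b = GeneSet("b", frozenset("uvw"))
        assert venn_partition(a, b).both == 0

    def test_hypergeom_enumeration_case(self):
        res = overlap_hypergeometric(5, 5, 5, 10)
        assert res.p == pytest.approx(1 / 252)

    def test_hypergeom_zero_overlap_is_one(self):
        assert overlap_hypergeometric(30, 40, 0, 500).p == pytest.approx(1.0)

    def test_hypergeom_inconsistent_counts(self):
        with pytest.raises(ValueError):
            overlap_hypergeometric(5, 5, 6, 10)
        with pytest.raises(ValueError):
            overlap_hypergeometric(50, 5, 2, 10)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_hypergeom_matches_pmf_summation(self, data):
        universe = data.draw(st.integers(10, 2000))
        size_a = data.draw(st.integers(1, universe))
        size_b = data.draw(st.integers(1, universe))
        overlap = data.draw(st.integers(0, min(size_a, size_b)))
        res = overlap_hypergeometric(size_a, size_b, overlap, universe)
        expected = hypergeom.sf(overlap - 1, universe, size_a, size_b)
        assert res.p == pytest.approx(expected, rel=1e-9, abs=1e-300)


class TestProjection:
    def test_toy_categories(self):
        genes = [f"g{i}" for i in range(6)]

        def mk(fdr, lfc):
            return DEResult(pd.DataFrame({
                "log2_fc": lfc, "p_value": fdr, "fdr": fdr,
                "direction": np.where(np.array(lfc) >= 0, "up", "down"),
                "is_constant": False}, index=genes))

        de_a = mk([0.01, 0.01, 0.5, 0.01, 0.5, 0.01],
                  [3.0, 2.5, 1.0, 2.4, 0.1, -2.5])
        de_b = mk([0.01, 0.5, 0.01, 0.01, 0.5, 0.01],
                  [2.6, 1.0, 3.0, 2.9, 0.2, 2.8])
        out = projection_categories(de_a, de_b)
        assert list(out["category"]) == ["both", "a_only", "b_only", "both",
                                         "ns", "both"]
        assert out["discordant"].sum() == 1  # g5: down in A, up in B

    def test_universe_mismatch(self):
        t1 = pd.DataFrame({"log2_fc": [1.0], "fdr": [0.5], "p_value": [0.5],
                           "direction": ["up"], "is_constant": [False]},
                          index=["g0"])
        t2 = t1.copy()
        t2.index = ["other"]
        with pytest.raises(ValueError, match="universe"):
            projection_categories(DEResult(t1), DEResult(t2))
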