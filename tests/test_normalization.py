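"""Filtering, CPM and TMM normalization, with an independent TMM oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from fightsync import (ExpressionMatrix, NormalizationFactors, cpm,
                       filter_low_expression, log_transform, tmm_factors,
                       tmm_values)


def _matrix(rows, samples=None):
    rows = np.asarray(rows)
    samples = samples or [f"s{i}" for i in range(rows.shape[1])]
    return pd.DataFrame(rows, index=[f"g{i}" for i in range(rows.shape[0])],
                        columns=samples)


class TestCpm:
    def test_known_values(self):
        counts = _matrix([[1, 50], [999_999, 99_950]])
        out = cpm(counts).values
        assert out.iloc[0, 0] == pytest.approx(1.0)
        assert out.iloc[0, 1] == pytest.approx(500.0)

    def test_zero_sum_column_names_sample(self):
        counts = _matrix([[1, 0], [2, 0]], samples=["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            cpm(counts)


class TestFilter:
    def test_boundary_and_zero_genes(self):
        counts = _matrix([[0, 0], [1, 0], [5, 5]])
        counts.iloc[1, 0] = 1
        lib = counts.sum(axis=0)
        # pad so library sizes are exactly 1e6 and CPM of count 1 is 1
        counts.loc["pad"] = [1_000_000 - lib["s0"], 1_000_000 - lib["s1"]]
        kept = filter_low_expression(counts)
        assert "g0" not in kept.index          # all-zero gene removed
        assert "g1" in kept.index              # CPM == 1 boundary inclusive
        assert list(kept.columns) == list(counts.columns)

    def test_three_gene_example(self):
        counts = _matrix([[0, 0], [1, 0], [5, 5]])
        counts.loc["pad"] = [999_994, 999_995]
        kept = filter_low_expression(counts)
        assert set(kept.index) == {"g1", "g2", "pad"}

    def test_idempotent(self, sim_data):
        counts, _, _ = sim_data
        once = filter_low_expression(counts)
        assert filter_low_expression(once).equals(once)


def _tmm_oracle(counts: pd.DataFrame, reference: str,
                trim_m: float = 0.30, trim_a: float = 0.05) -> pd.Series:
    """Brute-force TMM: explicit M/A trimming via pandas ranks."""
    lib = counts.sum(axis=0).astype(float)
    factors = {}
    for s in counts.columns:
        obs, ref = counts[s].astype(float), counts[reference].astype(float)
        mask = (obs > 0) & (ref > 0)
        po, pr = obs[mask] / lib[s], ref[mask] / lib[reference]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        var = ((lib[s] - obs[mask]) / (lib[s] * obs[mask])
               + (lib[reference] - ref[mask]) / (lib[reference] * ref[mask]))
        n = len(m)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
        rm = pd.Series(m).rank()
        ra = pd.Series(a).rank()
        keep = (rm.values >= lo_m) & (rm.values <= hi_m) \
            & (ra.values >= lo_a) & (ra.values <= hi_a)
        w = 1.0 / var.values[keep]
        factors[s] = 2.0 ** (np.sum(w * m.values[keep]) / np.sum(w))
    out = pd.Series(factors)
    return out / np.exp(np.mean(np.log(out)))


class TestTmm:
    def test_identical_columns(self):
        counts = _matrix([[10, 10], [200, 200], [3000, 3000], [40, 40]])
        f = tmm_factors(counts).table["factor"]
        assert np.allclose(f, 1.0)

    def test_proportional_columns(self, toy_counts):
        f = tmm_factors(toy_counts).table["factor"]
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        mu = rng.lognormal(4, 1.5, 500)
        counts = pd.DataFrame(
            {f"s{i}": rng.poisson(rng.gamma(5, mu / 5) * rng.uniform(0.5, 2))
             for i in range(6)},
            index=[f"g{i}" for i in range(500)])
        ours = tmm_factors(counts, reference="s0").table["factor"]
        oracle = _tmm_oracle(counts, "s0")
        assert np.allclose(ours, oracle[ours.index], atol=1e-6)

    def test_geometric_mean_one(self, sim_data):
        counts, _, _ = sim_data
        f = tmm_factors(filter_low_expression(counts)).table["factor"]
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_scale_equivariance_on_proportional_toy(self, toy_counts):
        # rescaling one library leaves TMM values unchanged when the log
        # ratios are constant (the precision weights are library-size
        # dependent, so exact equivariance needs a trim-free toy)
        scaled = toy_counts.copy()
        scaled["s1"] *= 4
        with pytest.warns(UserWarning):
            v1 = tmm_values(toy_counts, tmm_factors(toy_counts)).values
            v2 = tmm_values(scaled, tmm_factors(scaled)).values
        assert np.allclose(v1, v2, rtol=1e-9)

    def test_scale_equivariance_approximate_at_scale(self, sim_data):
        counts = filter_low_expression(sim_data[0]).copy()
        scaled = counts.copy()
        scaled.iloc[:, 0] *= 4
        v1 = tmm_values(counts, tmm_factors(counts)).values
        v2 = tmm_values(scaled, tmm_factors(scaled)).values
        assert np.allclose(v1, v2, rtol=0.02)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="two samples"):
            tmm_factors(_matrix([[1], [2]]))

    def test_few_genes_warns_untrimmed(self):
        counts = _matrix(np.arange(1, 11).reshape(5, 2) * 100)
        with pytest.warns(UserWarning, match="trimming"):
            tmm_factors(counts)


class TestTmmValues:
    def test_factor_one_equals_cpm(self, toy_counts):
        lib = toy_counts.sum(axis=0).astype(float)
        table = pd.DataFrame({"lib_size": lib, "factor": 1.0,
                              "effective_lib_size": lib})
        out = tmm_values(toy_counts, NormalizationFactors(table))
        assert np.allclose(out.values, cpm(toy_counts).values)

    def test_sample_mismatch_rejected(self, toy_counts):
        factors = tmm_factors(toy_counts)
        with pytest.raises(ValueError, match="sample sets"):
            tmm_values(toy_counts[["s2", "s1"]], factors)

    def test_nonunit_geomean_factors_rejected(self):
        table = pd.DataFrame({"lib_size": [1e6, 1e6], "factor": [2.0, 1.0],
                              "effective_lib_size": [2e6, 1e6]},
                             index=["s1", "s2"])
        with pytest.raises(ValueError, match="geometric mean"):
            NormalizationFactors(table)


class TestLogTransform:
    def test_values_and_monotonicity(self):
        expr = ExpressionMatrix(_matrix([[0.0, 3.0], [1.0, 7.0]]))
        out = log_transform(expr)
        assert out.scale == "log2"
        assert out.values.iloc[0, 0] == 0.0
        assert out.values.iloc[0, 1] == 2.0
        assert (np.diff(out.values.values.ravel().argsort())
                == np.diff(expr.values.values.ravel().argsort())).all()

    def test_double_log_rejected(self):
        expr = log_transform(ExpressionMatrix(_matrix([[1.0]])))
        with pytest.raises(ValueError, match="already"):
            log_transform(expr)

    def test_pseudocount_positive(self):
        with pytest.raises(ValueError, match="pseudocount"):
            log_transform(ExpressionMatrix(_matrix([[1.0]])), pseudocount=0)
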