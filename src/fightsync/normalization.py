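"""Low-expression filtering and TMM normalization of RNA-seq counts.

"TMM value" throughout this package means CPM computed on the TMM-effective
library size (library size x TMM scaling factor) — the standard reading of
trimmed-mean-of-M-values normalization. Factors are computed from trimmed,
precision-weighted means of per-gene log2 ratios against a reference sample
and rescaled to geometric mean 1, with the canonical 30% M-trim / 5% A-trim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["ExpressionMatrix", "NormalizationFactors", "cpm",
           "filter_low_expression", "tmm_factors", "tmm_values",
           "log_transform"]

MIN_TRIMMED_GENES = 20


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression values with an explicit scale.

    ``scale`` is ``"linear"`` (non-negative normalized values) or ``"log2"``
    (log2(value + pseudocount)).
    """

    values: pd.DataFrame
    scale: str = "linear"
    pseudocount: float | None = None

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "linear" and (self.values.to_numpy() < 0).any():
            raise ValueError("linear expression values must be non-negative")


@dataclass
class NormalizationFactors:
    """Per-sample library sizes and TMM scaling factors (geo-mean 1)."""

    table: pd.DataFrame  # columns: lib_size, factor, effective_lib_size

    def __post_init__(self) -> None:
        t = self.table
        if (t["factor"] <= 0).any():
            raise ValueError("TMM factors must be positive")
        geo = np.exp(np.mean(np.log(t["factor"])))
        if abs(geo - 1.0) > 1e-9:
            raise ValueError(f"factors must have geometric mean 1 (got {geo})")


def _check_counts(counts: pd.DataFrame) -> np.ndarray:
    arr = counts.to_numpy()
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    colsum = arr.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"zero-sum count column(s): {bad}")
    return colsum


def cpm(counts: pd.DataFrame) -> ExpressionMatrix:
    """Counts per million on raw library sizes (column sums)."""
    colsum = _check_counts(counts)
    return ExpressionMatrix(counts / colsum * 1e6, scale="linear")


def filter_low_expression(counts: pd.DataFrame, min_cpm: float = 1.0,
                          min_samples: int = 1) -> pd.DataFrame:
    """Keep genes with CPM >= ``min_cpm`` in at least ``min_samples`` samples.

    The default reproduces the usual 'at least one count per million in at
    least one sample' filter. Gene order and the sample set are preserved;
    the comparison is inclusive (>=). Idempotent.
    """
    values = cpm(counts).values
    keep = (values >= min_cpm).sum(axis=1) >= min_samples
    return counts.loc[keep]


def _choose_reference(counts: pd.DataFrame) -> str:
    frac = counts / counts.sum(axis=0)
    uq = frac.quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def _tmm_one(obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
             trim_m: float, trim_a: float) -> float:
    """Trimmed weighted mean of M values of one sample vs the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        raise ValueError("no genes co-expressed with the reference sample")
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((o / n_obs) / (r / n_ref))
    a = 0.5 * np.log2((o / n_obs) * (r / n_ref))
    # inverse of the delta-method binomial variance of M
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(m)
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm, ra = rankdata(m), rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if keep.sum() < MIN_TRIMMED_GENES:
        warnings.warn("fewer than 20 genes survive TMM trimming; "
                      "falling back to the untrimmed weighted mean")
        keep = np.ones(n, bool)
    with np.errstate(divide="ignore"):
        inv_w = 1.0 / w[keep]
    f = np.sum(inv_w * m[keep]) / np.sum(inv_w)
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05,
                reference: str | None = None) -> NormalizationFactors:
    """TMM scaling factors for every sample, rescaled to geometric mean 1.

    ``reference=None`` picks the sample whose upper-quartile CPM is closest
    to the mean upper-quartile. Run on a low-expression-filtered matrix.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = pd.Series(_check_counts(counts), index=counts.columns, dtype=float)
    if reference is None:
        reference = _choose_reference(counts)
    elif reference not in counts.columns:
        raise ValueError(f"reference sample {reference!r} not in matrix")
    ref = counts[reference].to_numpy()
    factors = pd.Series(
        {s: _tmm_one(counts[s].to_numpy(), ref, lib[s], lib[reference],
                     trim_m, trim_a)
         for s in counts.columns}, dtype=float)
    factors /= np.exp(np.mean(np.log(factors)))
    table = pd.DataFrame({"lib_size": lib, "factor": factors,
                          "effective_lib_size": lib * factors})
    table.index.name = "sample_id"
    return NormalizationFactors(table)


def tmm_values(counts: pd.DataFrame, factors: NormalizationFactors
               ) -> ExpressionMatrix:
    """TMM-normalized CPM: counts / effective library size x 1e6."""
    if list(counts.columns) != list(factors.table.index):
        raise ValueError("sample sets of counts and factors differ")
    eff = factors.table["effective_lib_size"].to_numpy()
    return ExpressionMatrix(counts / eff * 1e6, scale="linear")


def normalize(counts: pd.DataFrame, min_cpm: float = 1.0, min_samples: int = 1
              ) -> tuple[pd.DataFrame, NormalizationFactors, ExpressionMatrix]:
    """Convenience: filter, compute factors, return TMM values."""
    filtered = filter_low_expression(counts, min_cpm, min_samples)
    factors = tmm_factors(filtered)
    return filtered, factors, tmm_values(filtered, factors)


def log_transform(expr: ExpressionMatrix, pseudocount: float = 1.0
                  ) -> ExpressionMatrix:
    """log2(value + pseudocount) of a linear expression matrix."""
    if expr.scale != "linear":
        raise ValueError("input is already log-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    out = np.log2(expr.values + pseudocount)
    return ExpressionMatrix(out, scale="log2", pseudocount=pseudocount)
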