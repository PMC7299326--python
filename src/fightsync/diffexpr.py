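"""Differential expression against the non-fighting baseline, plus set stats.

Fight-responsive genes are called by comparing each fighting group (D20,
D60) with the baseline group B on log2 TMM values. The default test is a
per-gene Welch t-test on log2 TMM (``welch_log``); a negative-binomial
likelihood-ratio test with a per-gene method-of-moments dispersion
(``nb_lrt``) is available for count-level inference. Two threshold
profiles are exposed: ``characterization`` (FDR <= 0.05 and |log2 FC| > 2,
the stringent DEG list) and ``sync_input`` (FDR <= 0.05 and log2 FC > 0,
the permissive up-regulated list feeding the synchrony analysis).

Set-level statistics: Venn partition of two DEG lists, an upper-tail
hypergeometric overlap test evaluated in log space (representable far below
1e-300), and the projection of one contrast's calls onto the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .normalization import ExpressionMatrix, tmm_factors

__all__ = ["DEResult", "GeneSet", "de_test", "bh_fdr", "select_degs",
           "venn_partition", "overlap_hypergeometric", "projection_categories"]

PROFILES = {
    "characterization": dict(fdr_max=0.05, min_abs_lfc=2.0, direction="both"),
    "sync_input": dict(fdr_max=0.05, min_abs_lfc=0.0, direction="up"),
}


@dataclass
class DEResult:
    """Per-gene differential-expression calls for one contrast."""

    table: pd.DataFrame  # log2_fc, p_value, fdr, direction, is_constant
    contrast: tuple[str, str] = ("A", "B")
    method: str = "welch_log"


@dataclass
class GeneSet:
    label: str
    genes: frozenset[str]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _welch_log(log_vals_a: np.ndarray, log_vals_b: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(log_vals_b, log_vals_a, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    # zero variance in both groups: perfect separation (p=0) unless the
    # means agree, in which case the gene carries no signal (p=1)
    var0 = (log_vals_a.var(axis=1) == 0) & (log_vals_b.var(axis=1) == 0)
    diff = log_vals_b.mean(axis=1) - log_vals_a.mean(axis=1)
    p[var0 & (diff == 0)] = 1.0
    p[var0 & (diff != 0)] = 0.0
    return p


def _nb_lrt(counts: pd.DataFrame, samples_a: list[str], samples_b: list[str]
            ) -> np.ndarray:
    """NB likelihood-ratio p per gene with a method-of-moments dispersion.

    Counts are put on a common scale with TMM effective library sizes used
    as offsets; for a fixed per-gene dispersion the group means under null
    and alternative have closed-form (weighted) estimates, and the LRT
    statistic is referred to chi-square(1).
    """
    import statsmodels.api as sm

    sub = counts[samples_a + samples_b]
    eff = tmm_factors(sub).table["effective_lib_size"].to_numpy()
    offset = np.log(eff / 1e6)
    group = np.array([0] * len(samples_a) + [1] * len(samples_b))
    X_alt = np.column_stack([np.ones_like(group), group])
    X_null = np.ones((len(group), 1))
    pvals = np.empty(len(sub))
    y_all = sub.to_numpy()
    norm = y_all / (eff / 1e6)  # CPM-scale counts for moment matching
    for i, y in enumerate(y_all):
        mu = norm[i].mean()
        if mu == 0:
            pvals[i] = 1.0
            continue
        var = norm[i].var(ddof=1)
        phi = max((var - mu) / mu ** 2, 1e-8)
        fam = sm.families.NegativeBinomial(alpha=phi)
        try:
            fit_a = sm.GLM(y, X_alt, family=fam, offset=offset).fit()
            fit_0 = sm.GLM(y, X_null, family=fam, offset=offset).fit()
            lr = 2.0 * (fit_a.llf - fit_0.llf)
            pvals[i] = stats.chi2.sf(max(lr, 0.0), df=1)
        except Exception:
            pvals[i] = np.nan
    return pvals


def de_test(expr: ExpressionMatrix, group_a, group_b,
            counts: pd.DataFrame | None = None,
            method: str = "welch_log") -> DEResult:
    """Test genes for differential expression between two sample groups.

    ``expr`` must be log2-scale TMM values; ``group_a`` is the reference
    (baseline) group and log2 FC = mean(group_b) - mean(group_a), so
    positive values mean up-regulation in ``group_b``. FDR is BH over all
    tested genes. All-constant genes get p = 1 by convention and are
    flagged.
    """
    if expr.scale != "log2":
        raise ValueError("de_test expects log2-scale expression")
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least two samples")
    vals = expr.values
    missing = (set(group_a) | set(group_b)) - set(vals.columns)
    if missing:
        raise ValueError(f"samples absent from expression matrix: {sorted(missing)}")
    va = vals[group_a].to_numpy()
    vb = vals[group_b].to_numpy()
    lfc = vb.mean(axis=1) - va.mean(axis=1)

    if method == "welch_log":
        p = _welch_log(va, vb)
    elif method == "nb_lrt":
        if counts is None:
            raise ValueError("nb_lrt requires the raw count matrix")
        p = _nb_lrt(counts.loc[vals.index], group_a, group_b)
    else:
        raise ValueError(f"unknown method {method!r}")

    constant = np.ptp(np.concatenate([va, vb], axis=1), axis=1) == 0
    p = np.where(constant, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    table = pd.DataFrame({
        "log2_fc": lfc,
        "p_value": p,
        "fdr": bh_fdr(p),
        "direction": np.where(lfc >= 0, "up", "down"),
        "is_constant": constant,
    }, index=vals.index)
    return DEResult(table, contrast=("/".join(group_a[:1]) or "A",
                                     "/".join(group_b[:1]) or "B"),
                    method=method)


def select_degs(de: DEResult, profile: str = "characterization", *,
                fdr_max: float | None = None, min_abs_lfc: float | None = None,
                direction: str | None = None, label: str | None = None) -> GeneSet:
    """Select a DEG set under a named or custom threshold profile.

    ``characterization``: FDR <= 0.05 and |log2 FC| > 2 (both directions).
    ``sync_input``: FDR <= 0.05 and log2 FC > 0 (up only). Custom keyword
    thresholds override the profile values. FDR boundaries are inclusive,
    fold-change boundaries strict.
    """
    if profile not in PROFILES and (fdr_max is None or direction is None):
        raise ValueError(f"unknown profile {profile!r}")
    spec = dict(PROFILES.get(profile, {}))
    if fdr_max is not None:
        spec["fdr_max"] = fdr_max
    if min_abs_lfc is not None:
        spec["min_abs_lfc"] = min_abs_lfc
    if direction is not None:
        spec["direction"] = direction
    t = de.table
    sig = t["fdr"] <= spec["fdr_max"]
    if spec["direction"] == "up":
        sig &= t["log2_fc"] > spec["min_abs_lfc"]
    elif spec["direction"] == "down":
        sig &= t["log2_fc"] < -spec["min_abs_lfc"]
    else:
        sig &= t["log2_fc"].abs() > spec["min_abs_lfc"]
    return GeneSet(label or profile, frozenset(t.index[sig]),
                   provenance={"profile": profile, **spec,
                               "contrast": de.contrast, "method": de.method})


class VennCounts(NamedTuple):
    a_only: int
    b_only: int
    both: int

    @property
    def union(self) -> int:
        return self.a_only + self.b_only + self.both


def venn_partition(set_a: GeneSet, set_b: GeneSet) -> VennCounts:
    a, b = set(set_a.genes), set(set_b.genes)
    inter = len(a & b)
    return VennCounts(len(a) - inter, len(b) - inter, inter)


class OverlapTest(NamedTuple):
    p: float
    log10_p: float


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def overlap_hypergeometric(size_a: int, size_b: int, overlap: int,
                           universe: int) -> OverlapTest:
    """Upper-tail hypergeometric P(X >= overlap), evaluated via log-gamma.

    X is the overlap of a random ``size_a``-subset with a fixed
    ``size_b``-subset of a ``universe``-sized gene universe. Returned as
    (p, log10 p); the log form stays meaningful when p underflows 1e-300.
    """
    if min(size_a, size_b, overlap, universe) < 0 or \
            overlap > min(size_a, size_b) or max(size_a, size_b) > universe:
        raise ValueError("inconsistent overlap counts")
    k = np.arange(overlap, min(size_a, size_b) + 1)
    log_terms = (_log_comb(size_a, k) + _log_comb(universe - size_a, size_b - k)
                 - _log_comb(universe, size_b))
    log_p = logsumexp(log_terms)
    log10_p = float(log_p / np.log(10))
    return OverlapTest(float(min(np.exp(log_p), 1.0)), min(log10_p, 0.0))


def projection_categories(de_a: DEResult, de_b: DEResult,
                          profile: str = "characterization") -> pd.DataFrame:
    """Cross-tabulate the two contrasts' significance calls per gene.

    Category is ``ns`` / ``a_only`` / ``b_only`` / ``both``; the sign
    pattern records the log2 FC direction in each contrast, so discordant
    genes (up in one contrast, down in the other among ``both``) are
    countable.
    """
    ta, tb = de_a.table, de_b.table
    if not ta.index.equals(tb.index):
        raise ValueError("gene universes of the two contrasts differ")
    in_a = ta.index.isin(select_degs(de_a, profile).genes)
    in_b = tb.index.isin(select_degs(de_b, profile).genes)
    cat = np.select([in_a & in_b, in_a, in_b],
                    ["both", "a_only", "b_only"], default="ns")
    out = pd.DataFrame({
        "category": cat,
        "sign_a": ta["direction"],
        "sign_b": tb["direction"],
    }, index=ta.index)
    out["discordant"] = (out["category"] == "both") & (out["sign_a"] != out["sign_b"])
    return out
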