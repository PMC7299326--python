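"""Negative-binomial count simulator with pair-shared expression effects.

The generator emulates the statistical structure the downstream synchrony
analysis assumes: a lognormal landscape of baseline expression, a subset of
*responsive* genes whose expression shifts in fighting fish (log2 fold
change drawn per gene), and — nested inside those — *synchronized* genes
whose fight effect is partly shared by the two opponents of a pair.

On the log2 scale the relative expression of gene *g* in sample *s* is

    log2 q_gs = log2 lambda_g
              + F_s * [ LFC_g + w * u_{g, pair(s)} + (1 - w) * e_{g, s} ]

where ``F_s`` indicates a fighting sample, ``u`` is the pair-shared effect
(sd ``sigma_pair``), ``e`` the fish-specific effect (sd ``sigma_fish``) and
``w`` the pair-sharing weight of the sample's group (``sync_weight_d20`` or
``sync_weight_d60``) for synchronized genes, 0 for merely responsive ones.
Counts are then negative binomial with mean ``L_s * q_gs / sum_g q_gs`` and
per-gene dispersion ``phi_g`` (variance ``mu + phi * mu**2``).

Raising ``w`` moves the design from the weak-synchrony 20-minute regime to
the strong-synchrony 60-minute regime while leaving marginal expression
levels untouched — the knob the recovery experiments turn.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .design import FIGHT_GROUPS, validate_design

__all__ = ["SimParams", "simulate_counts"]


@dataclass
class SimParams:
    """Parameters of the count simulator; defaults give a desk-scale study."""

    n_genes: int = 2000
    baseline_logmean_mu: float = 8.0      # log2 scale
    baseline_logmean_sigma: float = 2.5
    #: scalar NB dispersion, or (lo, hi) for a per-gene log-uniform draw
    dispersion: float | tuple[float, float] = (0.02, 0.3)
    library_size_mean: float = 2.0e6
    library_size_cv: float = 0.1
    frac_responsive: float = 0.3
    frac_synchronized_of_responsive: float = 0.5
    lfc_mu: float = 2.0                   # log2 fold change of the fight response
    lfc_sigma: float = 1.0
    sigma_pair: float = 2.0               # sd of pair-shared log2 effect
    sigma_fish: float = 1.0               # sd of fish-specific log2 effect
    sync_weight_d20: float = 0.2
    sync_weight_d60: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            val = getattr(self, f.name)
            vals = val if isinstance(val, tuple) else (val,)
            if not all(math.isfinite(v) for v in vals):
                raise ValueError(f"non-finite parameter {f.name}={val!r}")
        for name in ("frac_responsive", "frac_synchronized_of_responsive",
                     "sync_weight_d20", "sync_weight_d60"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        disp = self.dispersion if isinstance(self.dispersion, tuple) else (self.dispersion,)
        if any(d <= 0 for d in disp):
            raise ValueError("dispersion must be positive")
        if self.sync_weight_d20 > self.sync_weight_d60:
            raise ValueError("sync_weight_d20 must not exceed sync_weight_d60")
        if self.n_genes < 1 or self.library_size_mean <= 0:
            raise ValueError("n_genes and library_size_mean must be positive")


@dataclass
class ExpressionGroundTruth:
    """Per-gene truth emitted alongside a simulated count matrix."""

    table: pd.DataFrame          # is_responsive, is_synchronized, true_lfc
    pair_effects: pd.DataFrame   # gene x pair_id shared effect u

    def __post_init__(self) -> None:
        t = self.table
        if (t["is_synchronized"] & ~t["is_responsive"]).any():
            raise ValueError("synchronized gene marked non-responsive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    # gamma-Poisson mixture: works for any real shape 1/phi
    shape = 1.0 / phi
    lam = rng.gamma(shape, phi * mean)
    return rng.poisson(lam)


def simulate_counts(design: pd.DataFrame, params: SimParams
                    ) -> tuple[pd.DataFrame, ExpressionGroundTruth]:
    """Simulate a gene-by-sample count matrix for a fighting-experiment design.

    Returns the count matrix (genes x samples, non-negative ints) and the
    ground truth (responsive/synchronized flags, true log2 fold changes,
    pair-shared effects). Identical (design, params) give identical output.
    """
    validate_design(design)
    rng = np.random.default_rng(params.seed)
    n_genes = params.n_genes
    genes = [f"g{i:05d}" for i in range(n_genes)]
    samples = design["sample_id"].tolist()
    n_samples = len(samples)

    lam_log2 = rng.normal(params.baseline_logmean_mu,
                          params.baseline_logmean_sigma, n_genes)
    if isinstance(params.dispersion, tuple):
        lo, hi = params.dispersion
        phi = np.exp(rng.uniform(np.log(lo), np.log(hi), n_genes))
    else:
        phi = np.full(n_genes, float(params.dispersion))

    n_resp = int(round(params.frac_responsive * n_genes))
    n_sync = int(round(params.frac_synchronized_of_responsive * n_resp))
    responsive_idx = rng.choice(n_genes, size=n_resp, replace=False)
    sync_idx = rng.choice(responsive_idx, size=n_sync, replace=False)
    is_responsive = np.zeros(n_genes, bool)
    is_responsive[responsive_idx] = True
    is_synchronized = np.zeros(n_genes, bool)
    is_synchronized[sync_idx] = True

    lfc = np.where(is_responsive, rng.normal(params.lfc_mu, params.lfc_sigma, n_genes), 0.0)

    pair_ids = design.loc[design["group"].isin(FIGHT_GROUPS), "pair_id"].unique().tolist()
    u = rng.normal(0.0, params.sigma_pair, (n_genes, len(pair_ids)))
    e = rng.normal(0.0, params.sigma_fish, (n_genes, n_samples))
    pair_col = {p: j for j, p in enumerate(pair_ids)}
    weight = {"D20": params.sync_weight_d20, "D60": params.sync_weight_d60}

    log2q = np.tile(lam_log2[:, None], (1, n_samples))
    for s_idx, row in enumerate(design.itertuples(index=False)):
        if row.group not in FIGHT_GROUPS:
            continue
        w_g = np.where(is_synchronized, weight[row.group], 0.0)
        effect = lfc + w_g * u[:, pair_col[row.pair_id]] + (1.0 - w_g) * e[:, s_idx]
        log2q[:, s_idx] += np.where(is_responsive, effect, 0.0)

    q = np.exp2(log2q)
    frac = q / q.sum(axis=0, keepdims=True)
    cv = params.library_size_cv
    if cv > 0:
        sigma2 = math.log1p(cv ** 2)
        mu_ln = math.log(params.library_size_mean) - sigma2 / 2.0
        lib = rng.lognormal(mu_ln, math.sqrt(sigma2), n_samples)
    else:
        lib = np.full(n_samples, params.library_size_mean)
    mean = frac * lib[None, :]
    counts = _nb_draw(rng, mean, phi[:, None])

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    truth_table = pd.DataFrame(
        {"is_responsive": is_responsive, "is_synchronized": is_synchronized,
         "true_lfc": lfc, "dispersion": phi},
        index=counts_df.index)
    pair_effects = pd.DataFrame(u, index=counts_df.index, columns=pair_ids)
    return counts_df, ExpressionGroundTruth(truth_table, pair_effects)
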