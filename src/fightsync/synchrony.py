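"""Transcriptome synchrony between the two opponents of fighting pairs.

The analysis treats every unordered pair of same-group samples as a *dyad*.
With five fighting pairs (10 fish) there are C(10,2) = 45 dyads: 5 *paired*
(the actual opponents) and 40 *unpaired*. Synchrony shows up in two ways:

* globally — Pearson correlations of log2 TMM profiles are higher for
  paired than for unpaired dyads (permutation test on the 45 r values);
* per gene — the expression distance
  ``D = |log10((x1 + eps) / (x2 + eps))`` between the two fish of a dyad is
  smaller for paired dyads (one-sided permutation test per gene; p < 0.05
  marks a *synchronized* gene).

Synchronized genes are then assigned to specific pairs: the gene's baseline
``B_i`` is the 25th percentile of its 40 unpaired distances, and the gene
counts as synchronized in pair j when ``D_ij < B_i`` (strict). The
resulting per-pair tallies quantify pair-specific individualization of the
brain-transcriptomic synchronization.

A caveat inherited from the procedure: the 45 dyads share samples (each
fish sits in 9 dyads), yet the permutation tests treat them as
exchangeable. Under a no-pair-effect null this dependence makes the
per-gene test conservative (it rejects below the nominal level).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .design import group_samples
from .diffexpr import GeneSet
from .normalization import ExpressionMatrix, log_transform, normalize
from .permutation import permutation_test

__all__ = ["PairingTable", "GeneDistanceTable", "SyncGeneResult",
           "enumerate_sample_pairs", "sample_correlations", "group_sync_test",
           "gene_pair_distances", "gene_sync_test", "sync_baseline",
           "assign_sync_pairs", "sync_pipeline", "top_variable_genes",
           "pair_coclustering"]


@dataclass
class PairingTable:
    """All same-group dyads with their paired/unpaired status."""

    table: pd.DataFrame  # sample_1, sample_2, is_paired, pair_id (paired only)
    group: str

    def __post_init__(self) -> None:
        t = self.table
        n = len(self.samples)
        if len(t) != n * (n - 1) // 2:
            raise ValueError("pairing table must hold all unordered dyads")

    @property
    def samples(self) -> list[str]:
        return sorted(set(self.table["sample_1"]) | set(self.table["sample_2"]))

    @property
    def n_paired(self) -> int:
        return int(self.table["is_paired"].sum())

    @property
    def dyad_labels(self) -> list[str]:
        return [f"{a}|{b}" for a, b in
                zip(self.table["sample_1"], self.table["sample_2"])]


@dataclass
class GeneDistanceTable:
    """Per-gene x per-dyad expression distances on the log10-ratio scale."""

    distances: pd.DataFrame  # genes x dyad labels
    pairing: PairingTable
    epsilon: float

    @property
    def is_paired(self) -> np.ndarray:
        return self.pairing.table["is_paired"].to_numpy()


@dataclass
class SyncGeneResult:
    """Synchronized-gene calls: permutation p, baseline, per-pair flags."""

    table: pd.DataFrame      # p_value, is_synchronized, baseline, sync_in_<pair>..., n_pairs_synchronized
    pair_ids: list[str]
    alpha: float

    @property
    def tally(self) -> dict[int, int]:
        """Number of synchronized genes by how many pairs they sync in."""
        sub = self.table.loc[self.table["is_synchronized"], "n_pairs_synchronized"]
        return {k: int((sub == k).sum()) for k in range(1, len(self.pair_ids) + 1)}


def enumerate_sample_pairs(design: pd.DataFrame, group: str) -> PairingTable:
    """All unordered dyads of a fighting group; paired = shared pair id."""
    sub = group_samples(design, group)
    if len(sub) < 2:
        raise ValueError("need at least two samples in the group")
    pair_of = dict(zip(sub["sample_id"], sub["pair_id"]))
    rows = []
    for a, b in combinations(sorted(sub["sample_id"]), 2):
        paired = pd.notna(pair_of[a]) and pair_of[a] == pair_of[b]
        rows.append((a, b, paired, pair_of[a] if paired else pd.NA))
    table = pd.DataFrame(rows, columns=["sample_1", "sample_2", "is_paired", "pair_id"])
    return PairingTable(table, group)


def sample_correlations(log_expr: ExpressionMatrix, pairing: PairingTable
                        ) -> pd.DataFrame:
    """Pearson r of log2 TMM profiles across genes, for every dyad."""
    if log_expr.scale != "log2":
        raise ValueError("sample_correlations expects log2-scale expression")
    vals = log_expr.values
    if len(vals) < 3:
        raise ValueError("need at least three genes")
    missing = set(pairing.samples) - set(vals.columns)
    if missing:
        raise ValueError(f"samples absent from expression: {sorted(missing)}")
    sub = vals[pairing.samples]
    sd = sub.std(axis=0)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"zero-variance sample(s): {list(flat.index)}")
    corr = sub.corr(method="pearson")
    out = pairing.table.copy()
    out["r"] = [corr.loc[a, b] for a, b in zip(out["sample_1"], out["sample_2"])]
    return out


def group_sync_test(correlations: pd.DataFrame, alternative: str = "greater",
                    mode: str = "exact_rank", n_mc: int = 100_000,
                    seed: int | None = None) -> float:
    """Permutation p for paired dyad correlations exceeding unpaired ones."""
    if correlations["is_paired"].sum() == 0 or (~correlations["is_paired"]).sum() == 0:
        raise ValueError("need both paired and unpaired dyads")
    return permutation_test(correlations["r"].to_numpy(),
                            correlations["is_paired"].to_numpy(),
                            alternative=alternative, mode=mode,
                            n_mc=n_mc, seed=seed)


def default_epsilon(values: pd.DataFrame) -> float:
    """Offset for zero expression: half the smallest positive value."""
    arr = values.to_numpy()
    pos = arr[arr > 0]
    if pos.size == 0:
        raise ValueError("expression matrix has no positive values")
    return float(pos.min()) / 2.0


def gene_pair_distances(expr: ExpressionMatrix, pairing: PairingTable,
                        epsilon: float | None = None) -> GeneDistanceTable:
    """|log10 ratio| expression distance per gene per dyad (linear TMM in)."""
    if expr.scale != "linear":
        raise ValueError("gene_pair_distances expects linear-scale TMM values")
    if epsilon is None:
        epsilon = default_epsilon(expr.values)
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    vals = expr.values
    a = vals[pairing.table["sample_1"].tolist()].to_numpy()
    b = vals[pairing.table["sample_2"].tolist()].to_numpy()
    d = np.abs(np.log10((a + epsilon) / (b + epsilon)))
    dist = pd.DataFrame(d, index=vals.index, columns=pairing.dyad_labels)
    return GeneDistanceTable(dist, pairing, float(epsilon))


def gene_sync_test(distances: GeneDistanceTable, alpha: float = 0.05,
                   alternative: str = "less", mode: str = "exact_rank",
                   n_mc: int = 100_000, seed: int | None = None) -> pd.DataFrame:
    """Per-gene permutation test: are paired distances smaller?

    Returns a frame with ``p_value`` and ``is_synchronized`` (strict
    p < alpha, as the synchronized-gene definition requires).
    """
    grp1 = distances.is_paired
    rows = np.asarray(distances.distances)
    pvals = np.empty(len(rows))
    for i, vals in enumerate(rows):
        pvals[i] = permutation_test(vals, grp1, alternative=alternative,
                                    mode=mode, n_mc=n_mc,
                                    seed=None if seed is None else seed + i)
    return pd.DataFrame({"p_value": pvals, "is_synchronized": pvals < alpha},
                        index=distances.distances.index)


def sync_baseline(distances: GeneDistanceTable) -> pd.Series:
    """Per-gene baseline B_i: 25th percentile of the unpaired distances.

    Percentile convention: linear interpolation at rank h = (n-1)p + 1 on
    the sorted values (so 1..40 gives 10.75).
    """
    unpaired = distances.distances.loc[:, ~distances.is_paired]
    if unpaired.shape[1] < 4:
        raise ValueError("need at least four unpaired dyads for the baseline")
    b = np.percentile(unpaired.to_numpy(), 25.0, axis=1,
                      method="linear")
    return pd.Series(b, index=distances.distances.index, name="baseline")


def assign_sync_pairs(distances: GeneDistanceTable, sync_flags: pd.Series,
                      baselines: pd.Series,
                      p_values: pd.Series | None = None,
                      alpha: float = 0.05) -> SyncGeneResult:
    """Assign each synchronized gene to the pairs where D_ij < B_i (strict).

    Non-synchronized genes get all-false flags and n_pairs = 0. Ties
    (D_ij == B_i) do not count as synchronized in that pair.
    """
    genes = distances.distances.index
    if not (sync_flags.index.equals(genes) and baselines.index.equals(genes)):
        raise ValueError("flags/baselines must cover exactly the distance genes")
    pt = distances.pairing.table
    paired = pt[pt["is_paired"]]
    pair_ids = paired["pair_id"].tolist()
    labels = [f"{a}|{b}" for a, b in zip(paired["sample_1"], paired["sample_2"])]
    d_paired = distances.distances[labels].to_numpy()
    flags = (d_paired < baselines.to_numpy()[:, None]) & \
        sync_flags.to_numpy(bool)[:, None]
    out = pd.DataFrame({"is_synchronized": sync_flags.to_numpy(bool),
                        "baseline": baselines.to_numpy()}, index=genes)
    if p_values is not None:
        out.insert(0, "p_value", p_values)
    for j, pid in enumerate(pair_ids):
        out[f"sync_in_{pid}"] = flags[:, j]
    out["n_pairs_synchronized"] = flags.sum(axis=1)
    return SyncGeneResult(out, pair_ids, alpha)


@dataclass
class SyncSummary:
    """End-to-end synchrony result for one fighting group."""

    result: SyncGeneResult
    group: str
    deg_set: GeneSet
    n_deg: int
    n_synchronized: int
    tally: dict[int, int]
    group_p: float
    correlations: pd.DataFrame
    epsilon: float

    @property
    def synchronized_fraction(self) -> float:
        return self.n_synchronized / self.n_deg if self.n_deg else float("nan")


def sync_pipeline(counts: pd.DataFrame, design: pd.DataFrame, group: str,
                  deg_set: GeneSet, alpha: float = 0.05,
                  mode: str = "exact_rank", epsilon: float | None = None,
                  seed: int | None = None, min_cpm: float = 1.0) -> SyncSummary:
    """Run normalization → distances → per-gene test → baseline → assignment.

    TMM normalization uses all samples of the count matrix (so values are
    comparable across groups); distances and tests are restricted to the
    given group's dyads and to ``deg_set`` genes.
    """
    filtered, factors, tmm = normalize(counts, min_cpm=min_cpm)
    missing = set(deg_set.genes) - set(filtered.index)
    if missing:
        raise ValueError(f"DEG set genes not in the expressed matrix: "
                         f"{sorted(missing)[:5]}...")
    pairing = enumerate_sample_pairs(design, group)
    log_tmm = log_transform(tmm)
    corr = sample_correlations(log_tmm, pairing)
    group_p = group_sync_test(corr, mode=mode, seed=seed)

    genes = [g for g in filtered.index if g in deg_set.genes]
    sub = ExpressionMatrix(tmm.values.loc[genes], scale="linear")
    if epsilon is None:
        epsilon = default_epsilon(tmm.values)  # full-matrix floor, logged
    if genes:
        dist = gene_pair_distances(sub, pairing, epsilon=epsilon)
        tested = gene_sync_test(dist, alpha=alpha, mode=mode, seed=seed)
        baselines = sync_baseline(dist)
        result = assign_sync_pairs(dist, tested["is_synchronized"], baselines,
                                   p_values=tested["p_value"], alpha=alpha)
    else:
        empty = pd.DataFrame(columns=["p_value", "is_synchronized", "baseline",
                                      "n_pairs_synchronized"])
        pair_ids = pairing.table.loc[pairing.table["is_paired"], "pair_id"].tolist()
        result = SyncGeneResult(empty, pair_ids, alpha)
    n_sync = int(result.table["is_synchronized"].sum()) if len(result.table) else 0
    return SyncSummary(result=result, group=group, deg_set=deg_set,
                       n_deg=len(genes), n_synchronized=n_sync,
                       tally=result.tally, group_p=group_p,
                       correlations=corr, epsilon=float(epsilon))


def top_variable_genes(log_expr: ExpressionMatrix, fraction: float) -> GeneSet:
    """Top ``floor(fraction * n)`` genes by log2 TMM standard deviation.

    Ties are broken lexicographically by gene id for determinism.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    vals = log_expr.values
    sd = vals.std(axis=1, ddof=1)
    order = sorted(vals.index, key=lambda g: (-sd[g], g))
    k = int(np.floor(fraction * len(order)))
    return GeneSet(f"top_{fraction:g}_variable", frozenset(order[:k]),
                   provenance={"fraction": fraction, "n_universe": len(order)})


def pair_coclustering(log_expr: ExpressionMatrix, design: pd.DataFrame,
                      group: str, genes: GeneSet | None = None,
                      method: str = "average"):
    """Cluster a group's samples; score pairs whose members are sisters.

    Hierarchical clustering with 1 - Pearson r distance. The score is the
    fraction of fighting pairs whose two opponents merge with each other
    before any other sample (sister leaves). Returns (score, linkage
    matrix, leaf order).
    """
    if log_expr.scale != "log2":
        raise ValueError("pair_coclustering expects log2-scale expression")
    sub = group_samples(design, group)
    samples = sub["sample_id"].tolist()
    vals = log_expr.values[samples]
    if genes is not None:
        vals = vals.loc[[g for g in vals.index if g in genes.genes]]
    if vals.std(axis=0).eq(0).any():
        raise ValueError("constant sample profile; correlation undefined")
    dist = 1.0 - vals.corr(method="pearson").to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    n = len(samples)
    sisters = {frozenset((int(a), int(b))) for a, b, _, _ in Z
               if a < n and b < n}
    idx = {s: i for i, s in enumerate(samples)}
    pairs = sub.dropna(subset=["pair_id"]).groupby("pair_id", observed=True)
    n_pairs, hits = 0, 0
    for _, members in pairs:
        ids = members["sample_id"].tolist()
        if len(ids) != 2:
            continue
        n_pairs += 1
        hits += frozenset((idx[ids[0]], idx[ids[1]])) in sisters
    score = hits / n_pairs if n_pairs else float("nan")
    return score, Z, samples


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Serialize a SciPy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(Z)

    def rec(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = rec(node.left), rec(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return rec(tree) + ";"
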