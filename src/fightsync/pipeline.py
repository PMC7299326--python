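"""End-to-end pipeline: simulate → normalize → DE → synchrony → behavior →
enrichment, with a machine-readable JSON report.

The report mirrors the study's bookkeeping: DEG counts per contrast, the
Venn partition and its hypergeometric overlap test, the dyad-correlation
permutation p per fighting group, synchronized-gene counts with the
by-how-many-pairs tally, pair-coclustering scores, and per-pair behavioral
summaries. Every run is fully determined by the seed in the config; the
config hash and seed are embedded in the report and in table headers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import diffexpr as de
from . import synchrony as sync
from .behavior_sim import BehaviorSimParams, simulate_behavior
from .design import FIGHT_GROUPS, simulate_design
from .diffexpr import GeneSet
from .enrichment import AnnotationTable, ora
from .normalization import log_transform, normalize
from .simulate import SimParams, simulate_counts

__all__ = ["PipelineConfig", "run_all", "write_report", "read_report"]

log = logging.getLogger("fightsync")

SCHEMA_VERSION = "1.0"


@dataclass
class PipelineConfig:
    """Knobs of the full pipeline; defaults give the desk-scale study."""

    seed: int = 0
    n_baseline: int = 5
    n_pairs_per_group: int = 5
    n_genes: int = 2000
    fdr_max: float = 0.05
    lfc_min: float = 2.0
    alpha: float = 0.05
    mode: str = "exact_rank"
    min_cpm: float = 1.0
    epsilon: float | None = None          # None: half the smallest positive TMM
    top_variable_fraction: float = 0.1
    sim: dict = field(default_factory=dict)        # SimParams overrides
    behavior_sim: dict = field(default_factory=dict)  # BehaviorSimParams overrides

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1 and 0 < self.alpha <= 1):
            raise ValueError("fdr_max and alpha must lie in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage=%s elapsed=%.2fs", name, time.time() - t0)
            return out
        return wrapper
    return deco


def _synthetic_annotation(truth, rng: np.random.Generator,
                          n_terms: int = 20, term_size: int = 30
                          ) -> AnnotationTable:
    """Annotation for the simulated genome: random terms plus one term
    concentrated in the truly synchronized genes (so enrichment has signal).
    """
    genes = truth.table.index.to_numpy()
    terms: dict[str, frozenset[str]] = {}
    for i in range(n_terms):
        size = min(term_size, len(genes))
        terms[f"T{i:03d}"] = frozenset(rng.choice(genes, size, replace=False))
    sync_genes = truth.table.index[truth.table["is_synchronized"]].to_numpy()
    if len(sync_genes):
        k = min(term_size, len(sync_genes))
        terms["T_sync"] = frozenset(rng.choice(sync_genes, k, replace=False))
    return AnnotationTable(terms)


@_stage("run_all")
def run_all(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the whole pipeline on simulated data; return the report.

    When ``outdir`` is given the intermediate tables (counts, design, DEG
    lists, per-gene synchrony table, event logs) are written there as
    TSV/CSV with provenance headers.
    """
    from . import io as fio

    rng = np.random.default_rng([config.seed, 0xF15])
    provenance = {"seed": config.seed, "config_hash": config.hash}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    design = simulate_design(config.n_baseline, config.n_pairs_per_group)
    sim_params = SimParams(n_genes=config.n_genes, seed=config.seed,
                           **config.sim)
    counts, truth = simulate_counts(design, sim_params)

    filtered, factors, tmm = normalize(counts, min_cpm=config.min_cpm)
    log_tmm = log_transform(tmm)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "config_hash": config.hash,
        "seed": config.seed,
        "n_genes_simulated": int(config.n_genes),
        "n_genes_expressed": int(len(filtered)),
        "contrasts": {},
        "sync": {},
        "behavior": {},
    }

    base = design.loc[design["group"] == "B", "sample_id"].tolist()
    char_sets: dict[str, GeneSet] = {}
    sync_sets: dict[str, GeneSet] = {}
    for group in FIGHT_GROUPS:
        fighters = design.loc[design["group"] == group, "sample_id"].tolist()
        result = de.de_test(log_tmm, base, fighters)
        char = de.select_degs(result, "characterization",
                              fdr_max=config.fdr_max, min_abs_lfc=config.lfc_min)
        sync_in = de.select_degs(result, "sync_input", fdr_max=config.fdr_max)
        char_sets[group], sync_sets[group] = char, sync_in
        tab = result.table
        report["contrasts"][f"B_vs_{group}"] = {
            "n_deg_characterization": len(char),
            "n_deg_sync_input": len(sync_in),
            "n_up": int(((tab["fdr"] <= config.fdr_max)
                         & (tab["log2_fc"] > config.lfc_min)).sum()),
            "n_down": int(((tab["fdr"] <= config.fdr_max)
                           & (tab["log2_fc"] < -config.lfc_min)).sum()),
        }

    venn = de.venn_partition(char_sets["D20"], char_sets["D60"])
    overlap = de.overlap_hypergeometric(len(char_sets["D20"]),
                                        len(char_sets["D60"]),
                                        venn.both, len(filtered))
    report["venn"] = {"d20_only": venn.a_only, "d60_only": venn.b_only,
                      "both": venn.both, "union": venn.union,
                      "overlap_p": overlap.p,
                      "overlap_log10_p": overlap.log10_p}

    truth_sync = set(truth.table.index[truth.table["is_synchronized"]])
    summaries: dict[str, sync.SyncSummary] = {}
    for group in FIGHT_GROUPS:
        summary = sync.sync_pipeline(counts, design, group, sync_sets[group],
                                     alpha=config.alpha, mode=config.mode,
                                     epsilon=config.epsilon, seed=config.seed,
                                     min_cpm=config.min_cpm)
        summaries[group] = summary
        tv = sync.top_variable_genes(log_tmm, config.top_variable_fraction)
        score, Z, leaves = sync.pair_coclustering(log_tmm, design, group, tv)
        called = set(summary.result.table.index[
            summary.result.table["is_synchronized"]])
        tested = set(summary.result.table.index)
        tp = len(called & truth_sync)
        fn = len((tested & truth_sync) - called)
        fp = len(called - truth_sync)
        tn = len(tested - truth_sync - called)
        report["sync"][group] = {
            "n_deg": summary.n_deg,
            "n_synchronized": summary.n_synchronized,
            "synchronized_fraction_pct": round(
                100.0 * summary.synchronized_fraction, 1)
            if summary.n_deg else None,
            "tally_by_n_pairs": {str(k): v for k, v in summary.tally.items()},
            "group_permutation_p": summary.group_p,
            "mean_r_paired": float(summary.correlations.loc[
                summary.correlations["is_paired"], "r"].mean()),
            "mean_r_unpaired": float(summary.correlations.loc[
                ~summary.correlations["is_paired"], "r"].mean()),
            "epsilon": summary.epsilon,
            "coclustering_score": score,
            "recovery": {"sensitivity": tp / (tp + fn) if tp + fn else None,
                         "specificity": tn / (tn + fp) if tn + fp else None},
        }
        if outdir is not None:
            out = Path(outdir)
            summary.result.table.to_csv(out / f"sync_{group}.tsv", sep="\t")
            (out / f"dendrogram_{group}.nwk").write_text(
                sync.linkage_to_newick(Z, leaves) + "\n")

    behavior_params = BehaviorSimParams(seed=config.seed, **config.behavior_sim)
    pair_rows = {}
    logs: list[pd.DataFrame] = []
    for group, duration in (("D20", 20.0), ("D60", 60.0)):
        params = dataclasses.replace(behavior_params, duration=duration)
        for pair_id in design.loc[design["group"] == group, "pair_id"].dropna().unique():
            event_log, tr = simulate_behavior(pair_id, params)
            logs.append(event_log.events)
            fo = bhv.first_occurrences(event_log).loc[pair_id]
            ml = bhv.mouthlock_summary(event_log).loc[pair_id]
            f1, f2 = tr["fish_ids"]
            try:
                r_bite = bhv.behavior_synchrony(
                    bhv.window_series(event_log, f1, "bite_strike"),
                    bhv.window_series(event_log, f2, "bite_strike"))
            except ValueError:
                r_bite = None
            pair_rows[pair_id] = {
                "group": group,
                "first_breath": fo.get("surface_breath"),
                "first_bite": fo.get("bite_strike"),
                "first_mouthlock": fo.get("mouth_lock"),
                "mouthlock_count": int(ml["count"]),
                "mouthlock_mean_duration": ml["mean_duration"],
                "mouthlock_time_fraction": ml["time_fraction"],
                "bite_sync_r": r_bite,
                "n_violations": int(len(bhv.interval_check(event_log))),
            }
    report["behavior"] = {k: {kk: (None if vv is None or
                                   (isinstance(vv, float) and np.isnan(vv))
                                   else vv)
                              for kk, vv in v.items()}
                          for k, v in pair_rows.items()}

    annotation = _synthetic_annotation(truth, rng)
    universe = GeneSet("expressed", frozenset(filtered.index))
    d60_table = summaries["D60"].result.table
    d60_sync_genes = (set(d60_table.index[d60_table["is_synchronized"]])
                      if len(d60_table) else set())
    enr = ora(GeneSet("sync_D60", frozenset(d60_sync_genes)), annotation,
              universe) if d60_sync_genes else pd.DataFrame()
    report["enrichment"] = {
        "n_terms_tested": int(len(enr)),
        "n_terms_significant": int(enr["significant"].sum()) if len(enr) else 0,
        "top_term": enr.iloc[0]["term"] if len(enr) else None,
    }

    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fio.write_counts(counts, out / "counts.tsv", header_comments=provenance)
        fio.write_design(design, out / "design.csv", header_comments=provenance)
        truth.table.to_csv(out / "ground_truth.tsv", sep="\t")
        events = pd.concat(logs, ignore_index=True)
        fio.write_events(events, out / "events.csv", duration_min=60.0,
                         header_comments=provenance)
        for group in FIGHT_GROUPS:
            fio.write_gene_set(char_sets[group].genes,
                               out / f"degs_characterization_{group}.txt")
            fio.write_gene_set(sync_sets[group].genes,
                               out / f"degs_sync_input_{group}.txt")
        write_report(report, out / "report.json")
    return report


def write_report(report: dict, path) -> None:
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("report lacks the current schema version")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=float) + "\n")


def read_report(path) -> dict:
    data = json.loads(Path(path).read_text())
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema version {version!r}")
    return data


def synchronized_fraction_pct(n_synchronized: int, n_deg: int) -> float:
    """Report arithmetic: synchronized share of the DEG list, in percent
    rounded to one decimal (so 1,522 of 2,409 gives 63.2)."""
    if n_deg <= 0:
        raise ValueError("n_deg must be positive")
    if not 0 <= n_synchronized <= n_deg:
        raise ValueError("synchronized count outside [0, n_deg]")
    return round(100.0 * n_synchronized / n_deg, 1)
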