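"""Experimental design: which samples exist and which ones fought each other.

The study layout is a baseline group of non-fighting fish (group ``B``, no
pair id) plus two fighting groups (``D20``, ``D60``), each consisting of
pairs of opponents sampled after a 20- or 60-minute fight. A design table
maps each sample to its group, fighting pair and fish.
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("B", "D20", "D60")
FIGHT_GROUPS = ("D20", "D60")


def simulate_design(n_baseline: int = 5, n_pairs_per_group: int = 5) -> pd.DataFrame:
    """Build the sample design of the fighting experiment.

    Parameters
    ----------
    n_baseline : number of non-fighting baseline fish (group B).
    n_pairs_per_group : number of fighting pairs in each of D20 and D60;
        every pair contributes two samples (the two opponents).

    Returns
    -------
    DataFrame with columns ``sample_id, group, pair_id, fish_id``. Baseline
    samples carry a missing pair id. Sample names follow the ``D60_41``
    pattern: group, pair number, fish number within the pair.
    """
    if n_baseline < 1 or n_pairs_per_group < 1:
        raise ValueError("need at least one baseline fish and one pair per group")
    rows = []
    for i in range(1, n_baseline + 1):
        rows.append((f"B{i}", "B", pd.NA, f"B{i}"))
    for group in FIGHT_GROUPS:
        for p in range(1, n_pairs_per_group + 1):
            pair = f"{group}_p{p}"
            for f in (1, 2):
                sid = f"{group}_{p}{f}"
                rows.append((sid, group, pair, sid))
    design = pd.DataFrame(rows, columns=["sample_id", "group", "pair_id", "fish_id"])
    design["pair_id"] = design["pair_id"].astype("string")
    return design


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check structural invariants of a design table; returns it unchanged."""
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    unknown = set(design["group"]) - set(GROUPS)
    if unknown:
        raise ValueError(f"unknown groups in design: {sorted(unknown)}")
    fighters = design[design["group"].isin(FIGHT_GROUPS)]
    sizes = fighters.groupby("pair_id", observed=True).size()
    bad = sizes[sizes != 2]
    if len(bad):
        raise ValueError(f"fighting pairs without exactly two samples: {list(bad.index)}")
    return design


def group_samples(design: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = design[design["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} absent from design")
    return sub.sort_values("sample_id").reset_index(drop=True)
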