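#!/usr/bin/env python
"""Summarize the simulated fight logs and opponent behavioral synchrony.

Per pair: first occurrence of each behavior, mouth-locking structure
(episode count, mean duration, share of the observation) and the Pearson
correlation of the two opponents' 2-minute-window bite/strike and
surface-breathing frequencies (1-minute step).
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from fightsync import EventLog
from fightsync import io as fio
from fightsync.behavior import (behavior_synchrony, first_occurrences,
                                interval_check, mouthlock_summary,
                                window_series)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/behavior"))
    args = ap.parse_args()

    events, _ = fio.read_events(args.datadir / "events.csv")
    args.outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pair_id, sub in events.groupby("pair_id"):
        duration = 20.0 if str(pair_id).startswith("D20") else 60.0
        log = EventLog(sub.reset_index(drop=True), duration)
        assert interval_check(log).empty, f"gating violated in {pair_id}"
        fo = first_occurrences(log).loc[pair_id]
        ml = mouthlock_summary(log).loc[pair_id]
        fish = sorted(sub["fish_id"].unique())
        sync_r = {}
        for behavior in ("bite_strike", "surface_breath"):
            try:
                sync_r[behavior] = behavior_synchrony(
                    window_series(log, fish[0], behavior),
                    window_series(log, fish[1], behavior))
            except ValueError:
                sync_r[behavior] = np.nan
        rows.append({"pair_id": pair_id, "duration_min": duration,
                     "first_breath": fo["surface_breath"],
                     "first_bite": fo["bite_strike"],
                     "first_mouthlock": fo["mouth_lock"],
                     "mouthlock_count": ml["count"],
                     "mouthlock_mean_duration": ml["mean_duration"],
                     "mouthlock_time_pct": 100 * ml["time_fraction"],
                     "bite_sync_r": sync_r["bite_strike"],
                     "breath_sync_r": sync_r["surface_breath"]})
    table = pd.DataFrame(rows).set_index("pair_id")
    table.to_csv(args.outdir / "pair_summaries.tsv", sep="\t")
    d60 = table[table["duration_min"] == 60.0]
    summary = {
        "n_pairs": len(table),
        "behavior_order_respected": bool(
            (d60["first_breath"] < d60["first_bite"]).all()
            and (d60["first_bite"] < d60["first_mouthlock"]).all()),
        "d60_mouthlock_count_mean": float(d60["mouthlock_count"].mean()),
        "d60_mouthlock_time_pct_mean": float(d60["mouthlock_time_pct"].mean()),
        "d60_bite_sync_r_mean": float(d60["bite_sync_r"].mean()),
    }
    (args.outdir / "summary.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"{len(table)} pairs: behaviors start in the order breath < bite "
          f"< mouth-lock ({summary['behavior_order_respected']}); 60-min "
          f"fights average {summary['d60_mouthlock_count_mean']:.1f} "
          f"mouth-locks covering {summary['d60_mouthlock_time_pct_mean']:.1f}% "
          f"of the fight; opponents' bite frequencies correlate at "
          f"r = {summary['d60_bite_sync_r_mean']:.2f}")


if __name__ == "__main__":
    main()
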