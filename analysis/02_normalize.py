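#!/usr/bin/env python
"""Filter low-expression genes and compute TMM-normalized expression.

Keeps genes with at least one count per million in at least one sample,
computes TMM scaling factors (geometric mean 1) and writes linear and
log2(TMM + 1) expression matrices.
"""

import argparse
from pathlib import Path

from fightsync import log_transform, normalize
from fightsync import io as fio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/normalized"))
    args = ap.parse_args()

    counts = fio.read_counts(args.datadir / "counts.tsv")
    filtered, factors, tmm = normalize(counts)
    args.outdir.mkdir(parents=True, exist_ok=True)
    factors.table.to_csv(args.outdir / "tmm_factors.tsv", sep="\t")
    tmm.values.to_csv(args.outdir / "tmm_values.tsv", sep="\t")
    log_transform(tmm).values.to_csv(args.outdir / "log2_tmm.tsv", sep="\t")

    spread = factors.table["factor"]
    print(f"kept {len(filtered)} of {len(counts)} genes after the CPM filter; "
          f"TMM factors span {spread.min():.3f}-{spread.max():.3f} "
          f"-> {args.outdir}")


if __name__ == "__main__":
    main()
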