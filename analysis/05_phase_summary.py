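#!/usr/bin/env python
"""Acrophase distribution of the mapped rhyQTL genes.

Takes the calls table from 02_map_rhyqtls.py, extracts the acrophase of the
most rhythmic genotype group of every called pair, classifies each as morning
(AM, peak in [0, 12)) or afternoon (PM, [12, 24)) and bins the phases into a
24-bin circular histogram. Writes results/phase_summary.tsv and
results/phase_histogram.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from rhyqtl.phase import classify_am_pm, phase_histogram


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--calls", type=Path, default=Path("results/rhyqtl_calls.tsv"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    calls = pd.read_csv(args.calls, sep="\t")
    hits = calls[calls["is_rhyqtl"]].copy()
    if hits.empty:
        print("no rhyQTL calls to summarize")
        return
    # phase of the most rhythmic genotype group (smallest fit p)
    pcols = [f"p_{g}" for g in (0, 1, 2)]
    best = hits[pcols].to_numpy(dtype=float)
    best_g = np.nanargmin(best, axis=1)
    hits["phase"] = [hits.iloc[i][f"phase_{g}"] for i, g in enumerate(best_g)]
    hits["am_pm"] = [classify_am_pm(p % 24) for p in hits["phase"]]

    summary = hits[["snp_id", "gene_id", "phase", "am_pm"]]
    summary.to_csv(args.out / "phase_summary.tsv", sep="\t", index=False)
    counts = phase_histogram(hits["phase"] % 24, n_bins=24)
    pd.DataFrame({"bin_start_h": np.arange(24), "count": counts}).to_csv(
        args.out / "phase_histogram.tsv", sep="\t", index=False)

    n_am = int((hits["am_pm"] == "AM").sum())
    print(f"{len(hits)} rhyQTL pairs: {n_am} AM, {len(hits) - n_am} PM")
    print(f"peak bins (h): {np.argsort(counts)[::-1][:3].tolist()}")
    print(f"tables written to {args.out}/")


if __name__ == "__main__":
    main()
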