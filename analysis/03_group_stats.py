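#!/usr/bin/env python
"""Group statistics over the ROI metrics: one-sample t vs chance,
Greenhouse-Geisser-corrected repeated-measures ANOVAs across the three
visual conditions, and post-hoc paired t-tests of AV incongruent against
the other visual conditions.

Reads results/pipeline/metrics.tsv (run analysis/02_roi_metrics.py first)
and prints the tests that establish the dissociation: significant accuracy
and reliability reductions for AV incongruent in V2, null effects for
similarity and amplitude.
"""

from pathlib import Path

import pandas as pd

from avmvpa.pipeline import group_statistics

METRICS = Path("results/pipeline/metrics.tsv")


def main() -> None:
    if not METRICS.exists():
        raise SystemExit("run analysis/02_roi_metrics.py first")
    metrics = pd.read_csv(METRICS, sep="\t")
    table = group_statistics(metrics)
    out = Path("results/group_statistics.tsv")
    table.to_csv(out, sep="\t", index=False, float_format="%.6g")
    pd.set_option("display.width", 120)
    for roi in ("V1", "V2", "V3"):
        print(f"\n=== {roi} ===")
        print(table[table.roi == roi].to_string(index=False))
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
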