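#!/usr/bin/env python
"""Score sleep for every cohort and build the LD sleep-parameter tables.

Reads the arena CSVs written by 01_simulate_cohorts.py (exercising the
same I/O path a real experiment would use), applies the viability screen,
scores bouts (inactivity >= 5 min at threshold 0 mm) and writes:

* results/sleep_per_fly_ld.csv — per-fly LD values (mean of the 2 LD days)
  for every parameter, by phase;
* results/sleep_group_summary.csv — mean +/- SD and median [min-max] per
  genotype x sex x phase x parameter, the layout of a sleep-parameter table.
"""

from pathlib import Path

import pandas as pd

from flysleep import LightProtocol, per_day_panel, viability_filter
from flysleep.io_formats import read_metadata_csv, read_zantiks_csv
from flysleep.pipeline import SLEEP_PARAMS, _group_summaries
from flysleep.sleep import ld_average

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    proto = LightProtocol()
    panels = []
    for cohort_dir in sorted(SCRATCH.iterdir()):
        recs = read_zantiks_csv(
            cohort_dir / "activity.csv",
            proto,
            read_metadata_csv(cohort_dir / "metadata.csv"),
        )
        dead = [r.fly_id for r in recs if not viability_filter(r).alive]
        if dead:
            print(f"{cohort_dir.name}: excluding dead flies {dead}")
        panels += [
            per_day_panel(r) for r in recs if viability_filter(r).alive
        ]
    panel = pd.concat(panels, ignore_index=True)
    per_fly = ld_average(panel, proto.ld_days)
    per_fly.to_csv(RESULTS / "sleep_per_fly_ld.csv", index=False)

    summary = _group_summaries(per_fly)
    summary.to_csv(RESULTS / "sleep_group_summary.csv", index=False)

    tst = summary[summary["parameter"] == "tst_min"]
    print("\nTST (min) per LD day, mean +/- SD by group and phase:")
    for _, r in tst.iterrows():
        print(
            f"  {r['genotype']:10s} {r['sex']:6s} {r['phase']}: "
            f"{r['mean']:6.1f} +/- {r['sd']:5.1f}  "
            f"(median {r['median']:.1f}, range {r['min']:.0f}-{r['max']:.0f})"
        )


if __name__ == "__main__":
    main()
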