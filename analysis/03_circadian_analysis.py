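#!/usr/bin/env python
"""Chi-square periodogram analysis of the DD segment (days 3-10).

Per fly: resample the DD activity to 5-min bins, scan candidate periods
16-32 h in 5-min steps, classify rhythmic/arrhythmic at alpha = 0.05 and
record peak period and rhythm power (Qp minus the significance line).

Writes results/circadian_per_fly.csv and results/circadian_group_summary.csv
and prints period-recovery diagnostics against the generator's ground truth
(true free-running period 23.7 h).
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from flysleep import LightProtocol
from flysleep.circadian import chi_square_periodogram, classify_group, dd_segment
from flysleep.io_formats import read_metadata_csv, read_zantiks_csv

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohorts"
RESULTS = ROOT / "results"


def main() -> None:
    proto = LightProtocol()
    rows = []
    summaries = []
    for cohort_dir in sorted(SCRATCH.iterdir()):
        recs = read_zantiks_csv(
            cohort_dir / "activity.csv",
            proto,
            read_metadata_csv(cohort_dir / "metadata.csv"),
        )
        truth = json.loads((cohort_dir / "ground_truth.json").read_text())
        pgs = []
        for r in recs:
            pg = chi_square_periodogram(dd_segment(r, 5.0), 5.0)
            pgs.append(pg)
            rows.append(
                {
                    "fly_id": r.fly_id,
                    "genotype": r.genotype,
                    "sex": r.sex,
                    "rhythmic": pg.rhythmic,
                    "period_h": pg.peak_period_h,
                    "power": pg.power,
                    "rhythmic_truth": truth[r.fly_id]["rhythmic"],
                }
            )
        g = classify_group(pgs, recs[0].genotype, recs[0].sex)
        summaries.append(g)
        print(
            f"{g.genotype:10s} {g.sex:6s}: {g.n_rhythmic}/{g.n} classified "
            f"rhythmic; period {g.period_mean:.2f} +/- {g.period_sd:.2f} h; "
            f"power median {g.power_median:.1f} "
            f"(range {g.power_min:.1f}-{g.power_max:.1f})"
        )
    per_fly = pd.DataFrame(rows)
    per_fly.to_csv(RESULTS / "circadian_per_fly.csv", index=False)
    pd.DataFrame([vars(s) for s in summaries]).to_csv(
        RESULTS / "circadian_group_summary.csv", index=False
    )

    truly = per_fly[per_fly["rhythmic_truth"]]
    err = (truly["period_h"] - 23.7).abs()
    print(
        f"\nperiod recovery over {len(truly)} truly rhythmic flies: "
        f"median |error| {err.median():.3f} h (grid step 1/12 h)"
    )
    false_pos = per_fly.loc[~per_fly["rhythmic_truth"], "rhythmic"]
    if len(false_pos):
        print(
            f"classified-rhythmic rate among truly arrhythmic flies: "
            f"{false_pos.mean():.2f} (n={len(false_pos)}) — the uncorrected "
            "16-32 h scan is strongly anticonservative; see docs/methods.md"
        )


if __name__ == "__main__":
    main()
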