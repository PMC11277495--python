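#!/usr/bin/env python
"""The statistical battery over the per-fly tables from steps 02-03.

Within each sex: Kruskal-Wallis + Dunn post hoc across the three genotypes
for every sleep parameter and phase, and (when both rhythmic and
arrhythmic flies occur) a chi-square test on rhythmicity counts.  Between
sexes of one genotype: Mann-Whitney.  A Shapiro-Wilk / Kolmogorov-Smirnov
normality screen is reported for the NT TST distributions as an advisory.

Writes results/comparisons.csv and results/normality_screen.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flysleep.group_stats import (
    multi_group_compare,
    normality_screen,
    rhythmicity_frequency_test,
    two_group_compare,
)
from flysleep.pipeline import SLEEP_PARAMS

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    per_fly = pd.read_csv(RESULTS / "sleep_per_fly_ld.csv")
    circ = pd.read_csv(RESULTS / "circadian_per_fly.csv")
    rows = []

    def emit(res, sex, parameter, phase):
        rows.append(
            {
                "test": res.test,
                "sex": sex,
                "parameter": parameter,
                "phase": phase,
                "groups": "|".join(res.groups),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "p_adjusted": res.p_adjusted,
                "significant": res.significant,
            }
        )

    genotypes = sorted(per_fly["genotype"].unique())
    for sex, by_sex in per_fly.groupby("sex"):
        for phase in sorted(by_sex["phase"].unique()):
            sub = by_sex[by_sex["phase"] == phase]
            for param in SLEEP_PARAMS:
                if param == "waso_min" and phase != "NT":
                    continue
                groups = {
                    gt: sub.loc[sub["genotype"] == gt, param].dropna().to_numpy()
                    for gt in genotypes
                }
                groups = {k: v for k, v in groups.items() if len(v) >= 2}
                if len(groups) < 2:
                    continue
                for res in multi_group_compare(groups):
                    emit(res, sex, param, phase)
        tab = np.array(
            [
                [
                    int(circ[(circ.genotype == gt) & (circ.sex == sex)].rhythmic.sum()),
                    int((~circ[(circ.genotype == gt) & (circ.sex == sex)].rhythmic).sum()),
                ]
                for gt in genotypes
            ]
        ).T
        if (tab.sum(axis=1) > 0).all():
            emit(
                rhythmicity_frequency_test(tab, tuple(genotypes)),
                sex, "rhythmicity_frequency", "DD",
            )
        else:
            print(
                f"{sex}: rhythmicity chi-square skipped (all flies classified "
                "rhythmic by the uncorrected scan)"
            )

    for gt in genotypes:
        for phase in ("DT", "NT"):
            sub = per_fly[(per_fly.genotype == gt) & (per_fly.phase == phase)]
            f = sub.loc[sub.sex == "female"]
            m = sub.loc[sub.sex == "male"]
            for param in SLEEP_PARAMS:
                if param == "waso_min" and phase != "NT":
                    continue
                a, b = f[param].dropna(), m[param].dropna()
                if len(a) < 2 or len(b) < 2:
                    continue
                emit(
                    two_group_compare(a, b, (f"{gt}/female", f"{gt}/male")),
                    "both", param, phase,
                )

    comp = pd.DataFrame(rows)
    comp.to_csv(RESULTS / "comparisons.csv", index=False)

    screen_rows = []
    for (gt, sex), g in per_fly[per_fly.phase == "NT"].groupby(["genotype", "sex"]):
        for res in normality_screen(g["tst_min"].dropna(), f"{gt}/{sex}"):
            screen_rows.append(
                {
                    "group": f"{gt}/{sex}",
                    "test": res.test,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "normality_rejected": res.significant,
                }
            )
    pd.DataFrame(screen_rows).to_csv(RESULTS / "normality_screen.csv", index=False)

    omni = comp[(comp.test == "Kruskal-Wallis") & (comp.parameter == "tst_min")]
    print("\nKruskal-Wallis, TST across genotypes:")
    for _, r in omni.iterrows():
        print(
            f"  {r['sex']:6s} {r['phase']}: H = {r['statistic']:.1f}, "
            f"p = {r['p_value']:.2e} {'*' if r['significant'] else ''}"
        )
    mw = comp[(comp.test == "Mann-Whitney") & (comp.parameter == "tst_min")]
    print("Mann-Whitney female vs male, TST:")
    for _, r in mw.iterrows():
        print(
            f"  {r['groups']:28s} {r['phase']}: U = {r['statistic']:.0f}, "
            f"p = {r['p_value']:.2e} {'*' if r['significant'] else ''}"
        )


if __name__ == "__main__":
    main()
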