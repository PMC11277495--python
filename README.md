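# flysleep

Circadian-rhythm and sleep analysis for fly locomotor recordings.

Video-tracking arenas record each fly's distance traveled (mm) per 30-s
bin, typically over 2 days of 12 h:12 h light–dark entrainment (lights-on
07:00 = Zeitgeber Time 00) followed by 8 days of constant darkness, the
free-running condition in which the endogenous clock expresses itself.
`flysleep` turns those series into the two standard readouts of
*Drosophila* chronobiology — the behavioral sleep parameter panel and
chi-square-periodogram rhythmicity — plus the group statistics used to
compare genotypes and sexes, and a ground-truthed synthetic cohort
generator so every stage is testable without access to recordings.

**Sleep** is behavioral inactivity lasting ≥ 5 min (threshold 0 mm by
default: micromovements count as wake; a 3-mm body-length option exists).
Per fly, day and phase (daytime DT = ZT00–ZT12, nighttime NT = ZT12–ZT24
on LD days; whole days in DD) the panel reports number of bouts, mean
bout length, total sleep time (TST), sleep latency from the phase start
(capped at 1440 min), wake after sleep onset

    WASO = 720 − (TST_NT − night latency)   [min]

and the sleep fragmentation index SFI = n_bouts / TST.

**Rhythmicity** uses the Sokolove–Bushell statistic on the DD segment at
5-min bins: folding the series at a candidate period of P bins over
K complete cycles,

    Qp = K · KP · Σ_h (M_h − M)² / Σ_i (X_i − M)² ,

χ²-distributed with P − 1 df under the no-rhythm null. A fly is rhythmic
when some candidate in the 16–32 h scan exceeds the χ²(0.95) line; its
free-running period is the peak candidate and its rhythm power the peak's
excess over the line. The scan applies no multiplicity correction —
faithful to field practice and *strongly anticonservative*; measured
rates and consequences are in [docs/methods.md](docs/methods.md).

**Group statistics**: mean ± SD and median [min–max] summaries,
chi-square on rhythmicity frequencies, Kruskal–Wallis with Dunn's
adjusted pairwise post hoc across genotypes, Mann–Whitney between sexes,
and an advisory Shapiro–Wilk / Lilliefors-KS normality screen (α = 0.05
throughout).

## Worked example

```python
import pandas as pd
from flysleep import SimConfig, simulate_group, per_day_panel, chi_square_periodogram
from flysleep.circadian import dd_segment
from flysleep.sleep import ld_average

cfg = SimConfig(n_flies=4, seed=7, genotype="wildtype", sex="female")
recs, truths, manifest = simulate_group(cfg)

panel = pd.concat([per_day_panel(r) for r in recs], ignore_index=True)
per_fly = ld_average(panel)          # per-fly means over the two LD days
print(per_fly[per_fly.phase == "NT"][
    ["fly_id", "n_bouts", "latency_min", "tst_min", "waso_min", "sfi"]
].round(2).to_string(index=False))

pg = chi_square_periodogram(dd_segment(recs[0]))
print(f"{recs[0].fly_id}: rhythmic={pg.rhythmic}, "
      f"period={pg.peak_period_h:.2f} h, power={pg.power:.1f}")
```

prints

```
             fly_id  n_bouts  latency_min  tst_min  waso_min  sfi
wildtype_female_000     15.5         27.5   402.25    345.25 0.04
wildtype_female_001     15.0         75.0   416.00    379.00 0.04
wildtype_female_002     13.0          1.0   438.00    283.00 0.03
wildtype_female_003     13.5         16.5   319.00    417.50 0.04

wildtype_female_000: rhythmic=True, period=23.42 h, power=309.5
```

Each row is one fly's nighttime panel averaged over its two LD days: the
first fly slept 402 min of the 720-min night across ~15.5 bouts, fell
asleep 27.5 min after lights-off, and its WASO satisfies
720 − (402.25 − 27.5) = 345.25 exactly. The periodogram classifies the
fly rhythmic with a free-running period of 23.4 h (true generative period
23.7 h, candidate grid 1/12 h) and a peak 309.5 Qp units above the
significance line.

## Analysis scripts

`analysis/` holds the numbered end-to-end drivers, each a thin narrative
over the library:

1. `01_simulate_cohorts.py` — six cohorts (wildtype-like, clockless-like,
   fxs-like × two sexes, n = 50), raw recordings under `scratch/`,
   design + ground truth in `results/cohort_manifest.csv`;
2. `02_sleep_analysis.py` — bout scoring, per-fly LD values and group
   summary tables;
3. `03_circadian_analysis.py` — periodograms, classification, period
   recovery against ground truth;
4. `04_group_comparisons.py` — the statistical battery;
5. `05_profiles_and_actograms.py` — average sleep profiles and a
   double-plotted actogram (`--figures` for PNGs).

The whole sequence runs in about a minute.

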