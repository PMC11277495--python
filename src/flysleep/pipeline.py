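"""End-to-end orchestration: cohort → sleep panel → periodograms → stats.

:func:`run_pipeline` takes either simulated cohorts or arena CSVs on disk,
applies the viability screen, scores sleep, classifies rhythmicity on the
DD segment, and writes tidy CSVs (per-fly panels, group summaries in the
mean ± SD / median [min–max] layout, comparison battery) plus a JSON run
log capturing every parameter.  All figure data are written as CSV first;
figures themselves are optional artifacts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from . import circadian, group_stats, sleep
from .io_formats import (
    ActivityRecording,
    LightProtocol,
    read_metadata_csv,
    read_zantiks_csv,
    viability_filter,
)
from .simulate import SimConfig, simulate_group

__all__ = ["RunConfig", "run_pipeline", "sleep_profile", "load_cohorts"]

SLEEP_PARAMS = [
    "n_bouts",
    "mean_bout_length_min",
    "latency_min",
    "tst_min",
    "waso_min",
    "sfi",
]


@dataclass(frozen=True)
class RunConfig:
    """Inputs and analysis parameters of one pipeline run."""

    sim_configs: tuple[SimConfig, ...] = ()
    input_csvs: tuple[tuple[str, str], ...] = ()  # (activity_csv, metadata_csv)
    protocol: LightProtocol = field(default_factory=LightProtocol)
    outdir: str = "results/pipeline"
    move_threshold: float = 0.0
    min_sleep_min: float = 5.0
    latency_cap_min: float = 1440.0
    periodogram_bin_min: float = 5.0
    period_range_h: tuple[float, float] = (16.0, 32.0)
    alpha: float = 0.05
    viability_lookback_h: float = 24.0
    profile_window_min: float = 30.0
    figures: bool = False


def load_cohorts(config: RunConfig) -> list[ActivityRecording]:
    recordings: list[ActivityRecording] = []
    for sim in config.sim_configs:
        recs, _, _ = simulate_group(sim)
        recordings.extend(recs)
    for activity_csv, metadata_csv in config.input_csvs:
        recordings.extend(
            read_zantiks_csv(
                activity_csv, config.protocol, read_metadata_csv(metadata_csv)
            )
        )
    return recordings


def sleep_profile(
    recordings: list[ActivityRecording],
    window_min: float = 30.0,
    move_threshold: float = 0.0,
    min_sleep_min: float = 5.0,
) -> pd.DataFrame:
    """Fraction of flies asleep per bin, boxcar-smoothed.

    The smoother is cyclic over the profiled span, so the smoothed profile
    conserves its integral exactly: the profile mean over a window equals
    the cohort's mean sleep fraction there.  Columns: time_h, fraction_asleep.
    """
    if not recordings:
        raise ValueError("no recordings")
    proto = recordings[0].protocol
    masks = np.array(
        [
            sleep.asleep_mask(r, move_threshold, min_sleep_min)
            for r in recordings
        ]
    )
    frac = masks.mean(axis=0)
    size = max(1, int(round(window_min * 60.0 / proto.bin_seconds)))
    smooth = uniform_filter1d(frac, size=size, mode="wrap")
    t_h = np.arange(len(frac)) * proto.bin_seconds / 3600.0
    return pd.DataFrame({"time_h": t_h, "fraction_asleep": smooth})


def _group_summaries(per_fly: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for (genotype, sex, phase), g in per_fly.groupby(
        ["genotype", "sex", "phase"]
    ):
        for param in SLEEP_PARAMS:
            if param == "waso_min" and phase != "NT":
                continue
            vals = g[param].to_numpy(dtype=float)
            if np.isnan(vals).all():
                continue
            s = group_stats.summarize(vals, genotype, sex, param)
            rows.append({**asdict_summary(s), "phase": phase})
    return pd.DataFrame(rows)


def asdict_summary(s: group_stats.GroupSummary) -> dict:
    return {
        "genotype": s.genotype,
        "sex": s.sex,
        "parameter": s.parameter,
        "n": s.n,
        "mean": s.mean,
        "sd": s.sd,
        "median": s.median,
        "min": s.min,
        "max": s.max,
    }


def _comparisons(per_fly: pd.DataFrame, circ: pd.DataFrame) -> pd.DataFrame:
    """The statistical battery over per-fly values.

    Within each sex: Kruskal–Wallis + Dunn across genotypes per sleep
    parameter and phase, and a chi-square test on rhythmicity counts.
    Between sexes of one genotype: Mann–Whitney per parameter.
    """
    rows: list[dict] = []

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
        for phase in by_sex["phase"].unique():
            sub = by_sex[by_sex["phase"] == phase]
            for param in SLEEP_PARAMS:
                if param == "waso_min" and phase != "NT":
                    continue
                groups = {
                    gt: sub.loc[sub["genotype"] == gt, param]
                    .dropna()
                    .to_numpy()
                    for gt in genotypes
                }
                groups = {k: v for k, v in groups.items() if len(v) >= 2}
                if len(groups) < 2:
                    continue
                for res in group_stats.multi_group_compare(groups):
                    emit(res, sex, param, phase)
    # rhythmicity frequency: chi-square across genotypes within sex
    for sex, by_sex in circ.groupby("sex"):
        tab = []
        gts = sorted(by_sex["genotype"].unique())
        for gt in gts:
            g = by_sex[by_sex["genotype"] == gt]
            tab.append([int(g["rhythmic"].sum()), int((~g["rhythmic"]).sum())])
        table = np.array(tab, dtype=int).T
        # chi-square is undefined when a margin is empty (e.g. every fly
        # classified rhythmic); skip the test rather than fake a p-value
        if len(gts) >= 2 and (table.sum(axis=1) > 0).all():
            res = group_stats.rhythmicity_frequency_test(table, tuple(gts))
            emit(res, sex, "rhythmicity_frequency", "DD")
    # sex contrasts within genotype
    for gt in genotypes:
        for phase in per_fly["phase"].unique():
            sub = per_fly[
                (per_fly["genotype"] == gt) & (per_fly["phase"] == phase)
            ]
            sexes = sorted(sub["sex"].unique())
            if len(sexes) != 2:
                continue
            for param in SLEEP_PARAMS:
                if param == "waso_min" and phase != "NT":
                    continue
                a = sub.loc[sub["sex"] == sexes[0], param].dropna().to_numpy()
                b = sub.loc[sub["sex"] == sexes[1], param].dropna().to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                res = group_stats.two_group_compare(
                    a, b, (f"{gt}/{sexes[0]}", f"{gt}/{sexes[1]}")
                )
                emit(res, "both", param, phase)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run the full analysis; returns the tables and writes them to disk."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    recordings = load_cohorts(config)
    viability = {
        r.fly_id: viability_filter(r, config.viability_lookback_h)
        for r in recordings
    }
    excluded = [fid for fid, v in viability.items() if not v.alive]
    alive = [r for r in recordings if viability[r.fly_id].alive]
    if excluded:
        warnings.warn(f"{len(excluded)} flies excluded as dead", stacklevel=2)

    panels = pd.concat(
        [
            sleep.per_day_panel(
                r,
                config.move_threshold,
                config.min_sleep_min,
                config.latency_cap_min,
            )
            for r in alive
        ],
        ignore_index=True,
    )
    per_fly = sleep.ld_average(panels, config.protocol.ld_days)

    circ_rows = []
    for r in alive:
        pg = circadian.chi_square_periodogram(
            circadian.dd_segment(r, config.periodogram_bin_min),
            config.periodogram_bin_min,
            config.period_range_h,
            config.alpha,
        )
        circ_rows.append(
            {
                "fly_id": r.fly_id,
                "genotype": r.genotype,
                "sex": r.sex,
                "rhythmic": pg.rhythmic,
                "period_h": pg.peak_period_h,
                "power": pg.power,
            }
        )
    circ = pd.DataFrame(circ_rows)

    rhythm_summary = pd.DataFrame(
        [
            asdict(
                circadian.classify_group(
                    [
                        circadian.chi_square_periodogram(
                            circadian.dd_segment(r, config.periodogram_bin_min),
                            config.periodogram_bin_min,
                            config.period_range_h,
                            config.alpha,
                        )
                        for r in alive
                        if r.genotype == gt and r.sex == sx
                    ],
                    gt,
                    sx,
                )
            )
            for gt, sx in sorted(
                {(r.genotype, r.sex) for r in alive}
            )
        ]
    )

    tables = {
        "sleep_per_day": panels,
        "sleep_per_fly_ld": per_fly,
        "sleep_group_summary": _group_summaries(per_fly),
        "circadian_per_fly": circ,
        "circadian_group_summary": rhythm_summary,
        "comparisons": _comparisons(per_fly, circ),
        "sleep_profile": sleep_profile(
            alive,
            config.profile_window_min,
            config.move_threshold,
            config.min_sleep_min,
        ),
    }
    for name, df in tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    log = {
        "n_recordings": len(recordings),
        "n_excluded_dead": len(excluded),
        "excluded": excluded,
        "parameters": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("sim_configs", "input_csvs")
        },
        "n_sim_groups": len(config.sim_configs),
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    if config.figures:
        _write_figures(alive, tables, outdir)
    return tables


def _write_figures(recordings, tables, outdir: Path) -> None:
    """Optional PNG artifacts (actogram, periodogram, sleep profile)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    figdir = outdir / "figures"
    figdir.mkdir(exist_ok=True)
    r = recordings[0]
    acto = circadian.build_actogram(r)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.imshow(acto.values, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_xlabel("time (double-plotted)")
    ax.set_ylabel("day")
    ax.set_title(f"actogram {r.fly_id}")
    fig.savefig(figdir / "actogram.png", dpi=100)
    plt.close(fig)

    pg = circadian.chi_square_periodogram(circadian.dd_segment(r))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(pg.test_periods_h, pg.qp, label="Qp")
    ax.plot(pg.test_periods_h, pg.signif_line, "r", label="alpha=0.05")
    ax.set_xlabel("period (h)")
    ax.set_ylabel("Qp")
    ax.legend()
    fig.savefig(figdir / "periodogram.png", dpi=100)
    plt.close(fig)

    prof = tables["sleep_profile"]
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(prof["time_h"], prof["fraction_asleep"])
    ax.set_xlabel("time (h)")
    ax.set_ylabel("fraction asleep")
    ax.set_ylim(0, 1)
    fig.savefig(figdir / "sleep_profile.png", dpi=100)
    plt.close(fig)
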