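"""Synthetic fly locomotor recordings with full ground truth.

The generator is a two-state (wake/sleep) semi-Markov process sampled per
30-s bin.  Per-bin transition probabilities are the reciprocal of
phase-dependent mean dwell times (geometric dwells, memoryless per bin),
modulated by a drive d(t) ∈ [−1, 1]:

* on LD days d(t) is the light square wave (+1 daytime, −1 nighttime) for
  every fly — light masks behavior whether or not the clock works;
* on DD days d(t) = s·cos(2π(t − 6 h)/τ): the endogenous oscillator of
  period τ (default 23.7 h) scaled by the fly's rhythm strength s, so a fly
  with s = 0 free-runs with constant rates and carries no rhythm at all.

Mean dwells interpolate geometrically between their day and night values as
a function of d(t); while awake, per-bin distance is a floor of about one
body length (``wake_floor_mm`` — a fly scored as moving traveled at least
its own length) plus an exponential whose mean is modulated by
(1 + activity_amplitude·d(t)), the overall mean resting at
``wake_activity_rate``; while asleep the emitted distance is exactly 0 (so
bout recovery by the scorer is exact), unless a sub-threshold micromovement
jitter is requested.

Every source of randomness derives from ``default_rng([seed, fly_index])``
— one master seed, per-fly streams by counter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    ActivityRecording,
    LightProtocol,
    write_metadata_csv,
    write_zantiks_csv,
)

__all__ = [
    "SleepPressure",
    "SimConfig",
    "FlyGroundTruth",
    "preset",
    "PRESETS",
    "simulate_fly",
    "simulate_group",
]


@dataclass(frozen=True)
class SleepPressure:
    """Mean dwell times (minutes) of the wake/sleep process, by phase."""

    dt_wake_mean_min: float
    dt_sleep_mean_min: float
    nt_wake_mean_min: float
    nt_sleep_mean_min: float

    def __post_init__(self) -> None:
        for v in (
            self.dt_wake_mean_min,
            self.dt_sleep_mean_min,
            self.nt_wake_mean_min,
            self.nt_sleep_mean_min,
        ):
            if not v > 0.5:
                raise ValueError("dwell means must exceed the bin width")


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated group.

    Defaults describe a wildtype-like cohort: 50 flies recorded for
    2 LD + 8 DD days at 30-s bins, free-running period 23.7 h, 90% of
    individuals rhythmic.
    """

    n_flies: int = 50
    seed: int = 0
    protocol: LightProtocol = field(default_factory=LightProtocol)
    true_period_h: float = 23.7
    rhythm_strength: float = 0.6
    fraction_rhythmic: float = 0.90
    wake_activity_rate: float = 20.0  # mean mm per active 30-s bin
    wake_floor_mm: float = 3.2  # an active fly travels >= ~1 body length
    activity_amplitude: float = 0.5
    sleep_pressure: SleepPressure = field(
        default_factory=lambda: SleepPressure(60.0, 12.0, 20.0, 25.0)
    )
    micromovement_mm: float = 0.0  # >0 adds sub-threshold jitter to sleep bins
    genotype: str = "wildtype"
    sex: str = "female"

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_rhythmic <= 1:
            raise ValueError("fraction_rhythmic must be in [0, 1]")
        if not 0 <= self.rhythm_strength <= 1:
            raise ValueError("rhythm_strength must be in [0, 1]")
        if self.wake_activity_rate <= 0:
            raise ValueError("wake_activity_rate must be > 0")
        if not 0 <= self.wake_floor_mm < self.wake_activity_rate:
            raise ValueError("wake_floor_mm must be in [0, wake_activity_rate)")
        if self.micromovement_mm >= max(self.wake_floor_mm, 1e-9) and self.micromovement_mm > 0:
            raise ValueError(
                "micromovement jitter must stay below the active-bin floor"
            )


# Presets target the qualitative group contrasts of the study design they
# emulate: a clock-mutant-like group with few rhythmic individuals and
# little day sleep, and an FXS-model-like group sleeping more in both
# phases with a weaker rhythm than wildtype.
PRESETS: dict[str, dict] = {
    "wildtype-like": dict(
        rhythm_strength=0.6,
        fraction_rhythmic=0.90,
        sleep_pressure=SleepPressure(60.0, 12.0, 20.0, 25.0),
    ),
    "clockless-like": dict(
        rhythm_strength=0.25,
        fraction_rhythmic=0.62,
        sleep_pressure=SleepPressure(120.0, 10.0, 22.0, 25.0),
    ),
    "fxs-like": dict(
        rhythm_strength=0.35,
        fraction_rhythmic=0.86,
        sleep_pressure=SleepPressure(25.0, 18.0, 12.0, 30.0),
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """A :class:`SimConfig` from a named preset, with overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return SimConfig(**{**PRESETS[name], **overrides})


@dataclass(frozen=True)
class FlyGroundTruth:
    fly_id: str
    rhythmic: bool
    true_period_h: float
    sleep_episodes: tuple[tuple[int, int], ...]  # half-open bin intervals


def _drive(config: SimConfig, strength: float) -> np.ndarray:
    proto = config.protocol
    t_h = np.arange(proto.total_bins) * proto.bin_seconds / 3600.0
    zt = t_h % 24.0
    is_ld = (t_h // 24.0).astype(int) < proto.ld_days
    light = np.where(zt < 12.0, 1.0, -1.0)
    osc = np.cos(2 * np.pi * (t_h - 6.0) / config.true_period_h)
    return np.where(is_ld, light, strength * osc)


def simulate_fly(
    config: SimConfig, fly_index: int
) -> tuple[ActivityRecording, FlyGroundTruth]:
    """Simulate one fly; deterministic for a fixed (seed, fly_index)."""
    rng = np.random.default_rng([config.seed, fly_index])
    rhythmic = bool(rng.random() < config.fraction_rhythmic)
    s = config.rhythm_strength if rhythmic else 0.0
    d = _drive(config, s)

    sp = config.sleep_pressure
    bin_min = config.protocol.bin_seconds / 60.0
    wake_g = np.sqrt(sp.dt_wake_mean_min * sp.nt_wake_mean_min)
    wake_r = np.sqrt(sp.dt_wake_mean_min / sp.nt_wake_mean_min)
    sleep_g = np.sqrt(sp.dt_sleep_mean_min * sp.nt_sleep_mean_min)
    sleep_r = np.sqrt(sp.dt_sleep_mean_min / sp.nt_sleep_mean_min)
    p_fall_asleep = np.clip(bin_min / (wake_g * wake_r**d), 1e-5, 0.95)
    p_wake_up = np.clip(bin_min / (sleep_g * sleep_r**d), 1e-5, 0.95)
    act_mean = (config.wake_activity_rate - config.wake_floor_mm) * np.clip(
        1.0 + config.activity_amplitude * d, 0.05, None
    )

    n = config.protocol.total_bins
    u = rng.random(n)
    wake_dist = config.wake_floor_mm + rng.exponential(act_mean)
    activity = np.zeros(n)
    asleep_bins = np.zeros(n, dtype=bool)
    asleep = False
    for i in range(n):
        if asleep:
            if u[i] < p_wake_up[i]:
                asleep = False
        elif u[i] < p_fall_asleep[i]:
            asleep = True
        asleep_bins[i] = asleep
        if not asleep:
            activity[i] = wake_dist[i]
    if config.micromovement_mm > 0:
        jitter = rng.uniform(0.0, config.micromovement_mm, size=n)
        activity[asleep_bins] = jitter[asleep_bins]

    edges = np.diff(np.concatenate(([0], asleep_bins.astype(int), [0])))
    episodes = tuple(
        (int(a), int(b))
        for a, b in zip(np.flatnonzero(edges == 1), np.flatnonzero(edges == -1))
    )
    fly_id = f"{config.genotype}_{config.sex}_{fly_index:03d}"
    rec = ActivityRecording(
        fly_id, config.genotype, config.sex, config.protocol, activity
    )
    truth = FlyGroundTruth(fly_id, rhythmic, config.true_period_h, episodes)
    return rec, truth


def simulate_group(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[list[ActivityRecording], list[FlyGroundTruth], pd.DataFrame]:
    """Simulate a cohort; optionally write it in the arena-CSV dialect.

    When ``outdir`` is given, writes ``activity.csv`` (wide arena CSV),
    ``metadata.csv`` (well → genotype/sex) and ``ground_truth.json``.
    Returns (recordings, ground truths, manifest).
    """
    if config.n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    pairs = [simulate_fly(config, i) for i in range(config.n_flies)]
    recordings = [p[0] for p in pairs]
    truths = [p[1] for p in pairs]
    manifest = pd.DataFrame(
        {
            "fly_id": [r.fly_id for r in recordings],
            "genotype": config.genotype,
            "sex": config.sex,
            "rhythmic_truth": [t.rhythmic for t in truths],
            "true_period_h": [
                t.true_period_h if t.rhythmic else np.nan for t in truths
            ],
            "n_sleep_episodes": [len(t.sleep_episodes) for t in truths],
        }
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_zantiks_csv(recordings, outdir / "activity.csv")
        write_metadata_csv(recordings, outdir / "metadata.csv")
        (outdir / "ground_truth.json").write_text(
            json.dumps(
                {
                    t.fly_id: {
                        "rhythmic": t.rhythmic,
                        "true_period_h": t.true_period_h,
                        "sleep_episodes": list(t.sleep_episodes),
                    }
                    for t in truths
                }
            )
        )
        manifest.to_csv(outdir / "manifest.csv", index=False)
    return recordings, truths, manifest
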