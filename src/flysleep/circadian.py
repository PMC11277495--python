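"""Chi-square periodogram analysis and actogram construction.

The rhythmicity statistic is the Sokolove–Bushell Qp.  For a series of N
analysis bins folded at a candidate period of P bins, with K = ⌊N/P⌋
complete cycles (N' = K·P bins used, the trailing partial cycle discarded),
column means M_h (h = 1..P) and grand mean M over the N' bins:

    Qp = K · N' · Σ_h (M_h − M)² / Σ_i (X_i − M)²

Under the no-rhythm null Qp is approximately χ² with P − 1 degrees of
freedom; a candidate is significant when Qp exceeds the χ²(1 − α) quantile.
A fly is *rhythmic* when any candidate in the scanned range exceeds its
significance line; its period is the candidate maximizing Qp minus the
line, and its rhythm *power* is that excess at the peak.

Caveat (documented, deliberate): following the source convention, no
multiple-testing correction is applied across candidate periods, which
makes the whole-scan classification strongly anticonservative; the
single-candidate test is calibrated.  See docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .io_formats import ActivityRecording

__all__ = [
    "Periodogram",
    "ActogramMatrix",
    "resample_activity",
    "chi_square_periodogram",
    "qp_single_period",
    "classify_group",
    "GroupRhythmicity",
    "build_actogram",
    "dd_segment",
]


@dataclass(frozen=True)
class Periodogram:
    test_periods_h: np.ndarray
    qp: np.ndarray
    signif_line: np.ndarray
    alpha: float
    peak_period_h: float  # NaN when arrhythmic
    power: float  # Qp − significance line at the peak; 0 when arrhythmic
    rhythmic: bool


@dataclass(frozen=True)
class ActogramMatrix:
    values: np.ndarray  # rows = days, columns = within-day bins
    modulo_period_h: float
    bin_min: float
    double_plot: bool


def resample_activity(
    activity: np.ndarray, bin_seconds: int, out_bin_min: float
) -> np.ndarray:
    """Sum activity into coarser non-overlapping bins (total conserved)."""
    ratio = out_bin_min * 60.0 / bin_seconds
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"output bin ({out_bin_min} min) must be a multiple of the "
            f"native bin ({bin_seconds} s)"
        )
    ratio = int(round(ratio))
    x = np.asarray(activity, dtype=float)
    if len(x) % ratio != 0:
        raise ValueError(
            f"series length {len(x)} is not a whole number of "
            f"{out_bin_min}-min bins"
        )
    return x.reshape(-1, ratio).sum(axis=1)


def qp_single_period(x: np.ndarray, period_bins: int) -> tuple[float, int]:
    """(Qp, degrees of freedom) at one candidate period, in analysis bins."""
    P = int(period_bins)
    N = len(x)
    K = N // P
    if K < 2:
        raise ValueError(
            f"need >= 2 complete cycles: {2 * P} bins required, have {N}"
        )
    xx = x[: K * P]
    M = xx.mean()
    denom = ((xx - M) ** 2).sum()
    if denom == 0:
        return 0.0, P - 1
    col_means = xx.reshape(K, P).mean(axis=0)
    qp = K * (K * P) * ((col_means - M) ** 2).sum() / denom
    return float(qp), P - 1


def chi_square_periodogram(
    activity: np.ndarray,
    bin_min: float = 5.0,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.05,
) -> Periodogram:
    """Scan candidate periods spaced one analysis bin apart.

    ``activity`` must already be at the analysis bin width (see
    :func:`resample_activity`).  A constant (e.g. all-zero) series carries
    no rhythm information and is returned as arrhythmic with zero power.
    """
    x = np.asarray(activity, dtype=float)
    lo, hi = period_range_h
    p_lo = int(round(lo * 60.0 / bin_min))
    p_hi = int(round(hi * 60.0 / bin_min))
    if p_lo < 2 or p_hi < p_lo:
        raise ValueError("invalid period range for this bin width")
    if len(x) < 2 * p_hi:
        raise ValueError(
            f"series too short: {2 * p_hi} bins required for the longest "
            f"candidate, have {len(x)}"
        )
    periods_bins = np.arange(p_lo, p_hi + 1)
    periods_h = periods_bins * bin_min / 60.0
    if np.ptp(x) == 0:
        zeros = np.zeros_like(periods_h)
        return Periodogram(
            periods_h, zeros, chi2.ppf(1 - alpha, periods_bins - 1), alpha,
            float("nan"), 0.0, False,
        )
    qp = np.empty(len(periods_bins))
    for i, P in enumerate(periods_bins):
        qp[i], _ = qp_single_period(x, P)
    line = chi2.ppf(1 - alpha, periods_bins - 1)
    excess = qp - line
    rhythmic = bool((excess > 0).any())
    if rhythmic:
        i = int(np.argmax(np.where(excess > 0, excess, -np.inf)))
        peak, power = float(periods_h[i]), float(excess[i])
    else:
        peak, power = float("nan"), 0.0
    return Periodogram(periods_h, qp, line, alpha, peak, power, rhythmic)


def dd_segment(
    recording: ActivityRecording, bin_min: float = 5.0
) -> np.ndarray:
    """The DD days of a recording, resampled to the analysis bin width."""
    proto = recording.protocol
    start = proto.ld_days * proto.bins_per_day
    return resample_activity(
        recording.activity[start:], proto.bin_seconds, bin_min
    )


@dataclass(frozen=True)
class GroupRhythmicity:
    genotype: str
    sex: str
    n: int
    n_rhythmic: int
    frequency: float
    period_mean: float
    period_sd: float
    period_median: float
    period_min: float
    period_max: float
    power_mean: float
    power_sd: float
    power_median: float
    power_min: float
    power_max: float


def _summary(v: np.ndarray) -> tuple[float, float, float, float, float]:
    if len(v) == 0:
        nan = float("nan")
        return nan, nan, nan, nan, nan
    return (
        float(np.mean(v)),
        float(np.std(v, ddof=1)) if len(v) > 1 else float("nan"),
        float(np.median(v)),
        float(np.min(v)),
        float(np.max(v)),
    )


def classify_group(
    periodograms: list[Periodogram], genotype: str, sex: str
) -> GroupRhythmicity:
    """Rhythmicity frequency plus period/power summaries over rhythmic flies.

    Period and power statistics intentionally exclude arrhythmic flies,
    whose peak period is undefined.
    """
    if not periodograms:
        raise ValueError("empty group")
    rhythmic = [p for p in periodograms if p.rhythmic]
    periods = np.array([p.peak_period_h for p in rhythmic])
    powers = np.array([p.power for p in rhythmic])
    return GroupRhythmicity(
        genotype,
        sex,
        len(periodograms),
        len(rhythmic),
        len(rhythmic) / len(periodograms),
        *_summary(periods),
        *_summary(powers),
    )


def build_actogram(
    recording: ActivityRecording,
    modulo_period_h: float = 24.0,
    actogram_bin_min: float = 30.0,
    double_plot: bool = True,
) -> ActogramMatrix:
    """Raster of daily activity traces, optionally double-plotted.

    Row i of a double plot concatenates day i and day i+1, the standard
    presentation for free-running rhythms; values are raw binned activity.
    """
    proto = recording.protocol
    x = resample_activity(
        recording.activity, proto.bin_seconds, actogram_bin_min
    )
    cols = int(round(modulo_period_h * 60.0 / actogram_bin_min))
    days = len(x) // cols
    if days < 1:
        raise ValueError("recording shorter than one plotting period")
    mat = x[: days * cols].reshape(days, cols)
    if double_plot:
        if days < 2:
            raise ValueError("double plot needs >= 2 days")
        mat = np.hstack([mat[:-1], mat[1:]])
    return ActogramMatrix(mat, modulo_period_h, actogram_bin_min, double_plot)
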