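"""Segment extraction, trial classification and the evaluation battery.

Blink-affected segments are 3-s windows anchored at each blink offset;
blink-free segments are 3-s chunks carved out of inter-blink intervals
longer than 6 s after dropping the first 3 s (which still carries the
previous blink's response).  On top of these the module provides blink-rate
time courses, trial-level response magnitudes, quantile-binned blink
response profiles, condition discriminability (ROC AUC), and a bootstrap
power analysis over trial counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .model import N_GRID, SEGMENT_GRID
from .preprocess import EDGE_TRANSIENT, BlinkTable, resample_window
from .signal_io import EventTable, PupilTrace

__all__ = [
    "Segment",
    "TrialRecord",
    "extract_segments",
    "classify_trials",
    "blink_rate_timecourse",
    "response_magnitudes",
    "quantile_bpr_profiles",
    "compare_to_blink_free",
    "discriminability",
    "power_bootstrap",
]


@dataclass
class Segment:
    """One 16-point analysis window (3 s at 5 Hz)."""

    values: np.ndarray
    kind: str                  # "blink_affected" | "blink_free"
    anchor: float              # blink offset (affected) or window start (free)
    isolated: bool = True      # nearest blink more than 3 s away
    overlapping: bool = False  # another blink inside the 3-s window
    blink_index: int = -1      # row in the BlinkTable, for affected segments

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_GRID,):
            raise ValueError(f"segment must have {N_GRID} values")


@dataclass
class TrialRecord:
    """Per-trial summary used by the discriminability and power analyses."""

    condition: object
    blink_history: tuple       # (2-back, 1-back, current) booleans
    magnitude: float
    run_id: str = ""


def extract_segments(
    trace: PupilTrace,
    blinks: BlinkTable,
    min_isolation: float = 3.0,
    free_gap: float = 6.0,
    edge_exclusion: float = EDGE_TRANSIENT,
) -> list[Segment]:
    """Extract blink-affected and blink-free 3-s segments from one run.

    A blink's segment starts at its offset and is flagged ``isolated`` iff
    the nearest neighbouring blink is more than ``min_isolation`` away.
    Blink-free segments come from inter-blink intervals longer than
    ``free_gap``: the first 3 s after the preceding blink are dropped, the
    rest is chunked into consecutive 3-s windows and the remainder
    discarded.  The first and last ``edge_exclusion`` seconds of the
    filtered run are excluded (filter edge transients).
    """
    t_start = trace.time[0] + edge_exclusion
    t_end = trace.time[-1] - edge_exclusion
    segments: list[Segment] = []
    onsets, offsets = blinks.onset, blinks.offset
    n_blinks = len(blinks)

    for j in range(n_blinks):
        t0 = offsets[j]
        if t0 < t_start or t0 + 3.0 > t_end:
            continue
        gap_prev = onsets[j] - offsets[j - 1] if j > 0 else np.inf
        gap_next = onsets[j + 1] - offsets[j] if j < n_blinks - 1 else np.inf
        isolated = min(gap_prev, gap_next) > min_isolation
        segments.append(
            Segment(
                values=resample_window(trace, t0),
                kind="blink_affected",
                anchor=float(t0),
                isolated=isolated,
                overlapping=not isolated,
                blink_index=j,
            )
        )

    # inter-blink intervals, including the stretches before the first and
    # after the last blink (no 3-s drop needed at the run start)
    bounds = []
    if n_blinks == 0:
        bounds.append((trace.time[0], trace.time[-1], False))
    else:
        bounds.append((trace.time[0], onsets[0], False))
        for j in range(n_blinks - 1):
            bounds.append((offsets[j], onsets[j + 1], True))
        bounds.append((offsets[-1], trace.time[-1], True))
    for lo, hi, after_blink in bounds:
        if hi - lo <= free_gap:
            continue
        usable_lo = lo + 3.0 if after_blink else lo
        usable_lo = max(usable_lo, t_start)
        usable_hi = min(hi, t_end)
        t0 = usable_lo
        while t0 + 3.0 <= usable_hi + 1e-9:
            segments.append(
                Segment(
                    values=resample_window(trace, t0),
                    kind="blink_free",
                    anchor=float(t0),
                )
            )
            t0 += 3.0
    return segments


def classify_trials(trials: EventTable, blinks: BlinkTable) -> np.ndarray:
    """Label each trial ``blink_free``/``blink_affected`` (or None).

    A trial is blink-free iff no blink onset falls within the span of the
    current, 1-back, or 2-back trial.  The first two trials of a run have
    an incomplete history and are left unlabeled (None).
    """
    n = len(trials)
    labels = np.empty(n, dtype=object)
    onsets = blinks.onset
    has_blink = np.array([
        bool(np.any((onsets >= trials.onset[i]) & (onsets < trials.onset[i] + trials.duration[i])))
        for i in range(n)
    ])
    for i in range(n):
        if i < 2:
            labels[i] = None
        elif has_blink[i] or has_blink[i - 1] or has_blink[i - 2]:
            labels[i] = "blink_affected"
        else:
            labels[i] = "blink_free"
    return labels


def blink_rate_timecourse(
    blinks: BlinkTable,
    trials: EventTable,
    rate: float,
    boxcar: float = 0.1,
) -> np.ndarray:
    """Within-trial blink-rate time course (Hz) over the trial grid.

    Blink-offset pulses are rastered per trial at the native sampling rate,
    averaged across trials, boxcar-smoothed, and scaled to blinks/s.
    Assumes a uniform trial duration.
    """
    duration = float(trials.duration[0])
    if not np.allclose(trials.duration, duration):
        raise ValueError("blink_rate_timecourse needs a uniform trial grid")
    n_samp = int(round(duration * rate))
    raster = np.zeros((len(trials), n_samp))
    for i in range(len(trials)):
        rel = blinks.offset - trials.onset[i]
        inside = (rel >= 0) & (rel < duration)
        idx = np.floor(rel[inside] * rate).astype(int)
        np.add.at(raster[i], idx, 1.0)
    mean_pulses = raster.mean(axis=0)
    width = max(1, int(round(boxcar * rate)))
    kernel = np.ones(width)
    num = np.convolve(mean_pulses, kernel, mode="same")
    den = np.convolve(np.ones(n_samp), kernel, mode="same")
    return (num / den) * rate  # per-sample probability -> Hz


def response_magnitudes(
    trials: EventTable,
    trace: PupilTrace,
    window: dict | None = None,
    normalization: str = "demean",
) -> list[TrialRecord]:
    """Window-averaged, baselined trial response magnitudes.

    The run is demeaned or z-scored, each trial is baselined at its onset
    sample, and the magnitude is the mean within a fixed window
    ``{"fixed": (start_s, end_s)}`` relative to trial onset, or within the
    span where the grand-average time course exceeds ``auto_frac`` of its
    maximum (``{"auto_frac": 0.75}``).
    """
    window = window or {"fixed": (0.5, float(trials.duration[0]))}
    pupil = trace.pupil.astype(float).copy()
    if normalization == "demean":
        pupil -= pupil.mean()
    elif normalization == "zscore":
        sd = pupil.std()
        pupil = (pupil - pupil.mean()) / (sd if sd > 0 else 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    rate = trace.rate
    t0 = trace.time[0]
    duration = float(trials.duration[0])
    n_samp = int(round(duration * rate))
    onset_idx = np.round((trials.onset - t0) * rate).astype(int)
    if np.any(onset_idx < 0) or np.any(onset_idx + n_samp > len(pupil)):
        raise ValueError("trials exceed trace span")
    courses = np.stack([pupil[i : i + n_samp] for i in onset_idx])
    courses = courses - courses[:, [0]]  # baseline at trial onset

    if "fixed" in window:
        lo, hi = window["fixed"]
        i0, i1 = int(round(lo * rate)), int(round(hi * rate))
        i1 = min(i1, n_samp)
    else:
        frac = float(window["auto_frac"])
        grand = courses.mean(axis=0)
        peak = grand.max()
        if peak <= 0 or np.ptp(grand) == 0:
            raise ValueError("flat grand average: auto window is empty")
        above = np.flatnonzero(grand >= frac * peak)
        i0, i1 = int(above[0]), int(above[-1]) + 1
    mags = courses[:, i0:i1].mean(axis=1)

    records = []
    for i in range(len(trials)):
        records.append(
            TrialRecord(
                condition=trials.condition[i],
                blink_history=(),
                magnitude=float(mags[i]),
                run_id=trace.run_id,
            )
        )
    return records


def quantile_bpr_profiles(
    segments_by_stratum: dict,
    n_quantiles: int = 5,
    trough_window: tuple = (0.5, 1.2),
    smooth: bool = True,
) -> dict:
    """Quantile-binned blink-response profiles with equal stratum weighting.

    Each segment's amplitude is its lowest value within ``trough_window``
    seconds after the blink offset.  Segments are binned into amplitude
    quantiles within each stratum (e.g. background-luminance group), then
    each quantile's profile is averaged across strata with equal weight.  A
    GCV-tuned cubic smoothing spline is applied before reading out the peak
    (most negative) amplitude and its time.
    """
    in_win = (SEGMENT_GRID >= trough_window[0]) & (SEGMENT_GRID <= trough_window[1])
    per_stratum = {}
    for stratum, segments in segments_by_stratum.items():
        mat = np.asarray([np.asarray(s.values if isinstance(s, Segment) else s) for s in segments])
        if mat.shape[0] < n_quantiles:
            warnings.warn(f"stratum {stratum!r} has fewer segments than quantiles; skipped",
                          stacklevel=2)
            continue
        amps = mat[:, in_win].min(axis=1)
        order = np.argsort(amps)
        bins = np.array_split(order, n_quantiles)
        per_stratum[stratum] = np.stack([mat[b].mean(axis=0) for b in bins])
    if not per_stratum:
        raise ValueError("no stratum had enough segments")
    profiles = np.mean(list(per_stratum.values()), axis=0)  # equal stratum weight

    peaks, peak_times, smoothed = [], [], []
    for q in range(n_quantiles):
        prof = profiles[q]
        if smooth:
            spl = make_smoothing_spline(SEGMENT_GRID, prof)
            fine_t = np.linspace(0, 3, 301)
            fine = spl(fine_t)
        else:
            fine_t, fine = SEGMENT_GRID, prof
        i = int(np.argmin(fine))
        peaks.append(float(fine[i]))
        peak_times.append(float(fine_t[i]))
        smoothed.append(fine)
    return {
        "profiles": profiles,
        "peak_amplitude": np.array(peaks),
        "time_to_peak": np.array(peak_times),
    }


def compare_to_blink_free(mean_affected: np.ndarray, mean_free: np.ndarray) -> float:
    """Euclidean distance between the mean affected and free profiles."""
    a = np.asarray(mean_affected, dtype=float)
    b = np.asarray(mean_free, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profile length mismatch")
    return float(np.linalg.norm(a - b))


def discriminability(magnitudes_a, magnitudes_b) -> dict:
    """Mean difference, pooled SEM and ROC AUC between two magnitude groups.

    The AUC is the Mann-Whitney statistic (#(a>b) + 0.5*#(a==b)) / (nA*nB);
    ties count one half.
    """
    a = np.asarray(magnitudes_a, dtype=float)
    b = np.asarray(magnitudes_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = a[:, None] - b[None, :]
    auc = (np.count_nonzero(diff > 0) + 0.5 * np.count_nonzero(diff == 0)) / diff.size
    pooled_sem = float(np.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size))
    return {
        "mean_diff": float(a.mean() - b.mean()),
        "pooled_SEM": pooled_sem,
        "AUC": float(auc),
    }


def power_bootstrap(
    records,
    coding: dict,
    n_grid,
    reps: int = 10_000,
    alpha: float = 0.01,
    target_frac: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Bootstrap power curve: rejection fraction of the slope test vs n.

    For each sample size ``n``, ``reps`` bootstrap samples of ``n`` trials
    are drawn with replacement from the pooled records, the magnitude is
    regressed on the coded condition (OLS), and the two-sided slope t-test
    is evaluated at ``alpha``.  Resamples with a single distinct regressor
    value count as non-significant.  Returns per-n rejection fractions and
    the smallest grid n reaching ``target_frac`` (None if not reached).
    """
    y_all = np.array([r.magnitude for r in records], dtype=float)
    x_all = np.array([coding[r.condition] for r in records], dtype=float)
    if np.unique(x_all).size < 2:
        raise ValueError("need at least 2 distinct regressor values")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    from scipy import stats as sps

    fractions = {}
    for n in n_grid:
        idx = rng.integers(0, len(y_all), size=(reps, n))
        x = x_all[idx]
        y = y_all[idx]
        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = np.sum((x - xm) ** 2, axis=1)
        sxy = np.sum((x - xm) * (y - ym), axis=1)
        ok = sxx > 0
        slope = np.where(ok, sxy / np.where(ok, sxx, 1.0), 0.0)
        resid = y - ym - slope[:, None] * (x - xm)
        dof = n - 2
        s2 = np.sum(resid**2, axis=1) / dof
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = slope / np.sqrt(s2 / np.where(ok, sxx, 1.0))
        pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
        reject = ok & np.isfinite(pvals) & (pvals < alpha)
        fractions[int(n)] = float(np.mean(reject))
    min_n = None
    for n in sorted(fractions):
        if fractions[n] >= target_frac:
            min_n = n
            break
    return {"fraction_significant": fractions, "min_n": min_n}
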