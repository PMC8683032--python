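"""End-to-end study workflows built from the library pieces.

These are the package's standard experiments on synthetic data: correction
efficacy against the blink-free reference, the closed-form confound
prediction versus trial-averaged simulation, comparator bias of linear
interpolation, and the bootstrap power comparison across correction
methods.  Each takes a seed and problem sizes and returns plain dicts of
numbers, so the same code drives the test suite, the acceptance script and
interactive use.
"""

from __future__ import annotations

import warnings

import numpy as np

from .correction import interpolate_blinks, subtract_bpr
from .evaluate import (
    blink_rate_timecourse,
    compare_to_blink_free,
    extract_segments,
    power_bootstrap,
    response_magnitudes,
)
from .inference import FitConfig, InsufficientDataError, fit_bpr_model
from .model import gamma_kernel
from .preprocess import preprocess_trace
from .simulate import (
    fixation_config,
    load_config,
    oddball_config,
    predict_confound,
    select_trial_sequences,
    synthesize_trace,
)

__all__ = [
    "correction_efficacy",
    "confound_prediction",
    "sequence_confound_signs",
    "comparator_bias",
    "power_comparison",
]


def correction_efficacy(
    n_runs: int = 100,
    seed: int = 0,
    duration: float = 240.0,
    rate: float = 50.0,
    blink_rate: float = 0.25,
) -> dict:
    """Fraction of runs where correction moves the blink-locked mean
    toward the blink-free mean.

    Each run is a fixation-style simulation; the model is fitted from
    scratch and its per-blink component subtracted.  The Euclidean distance
    between the mean blink-affected and mean blink-free 16-point profiles
    is compared before and after correction.  Runs where the fit fails
    count as not improved.
    """
    improved = []
    distances = []
    for i in range(n_runs):
        run_seed = seed * 100_003 + i
        cfg = fixation_config(duration=duration, rate=rate,
                              blink_rate=blink_rate, seed=run_seed % (2**31))
        trace, _, _, _ = synthesize_trace(cfg)
        try:
            filt, blinks = preprocess_trace(trace)
            model = fit_bpr_model(filt, blinks, FitConfig(seed=run_seed % (2**31)))
            corrected = subtract_bpr(filt, blinks, model).corrected
        except (InsufficientDataError, ValueError, RuntimeError):
            improved.append(False)
            continue
        segs = extract_segments(filt, blinks)
        segs_c = extract_segments(corrected, blinks)
        free = [s.values for s in segs if s.kind == "blink_free"]
        aff = [s.values for s in segs if s.kind == "blink_affected"]
        aff_c = [s.values for s in segs_c if s.kind == "blink_affected"]
        if not free or not aff:
            improved.append(False)
            continue
        mean_free = np.mean(free, axis=0)
        d_unc = compare_to_blink_free(np.mean(aff, axis=0), mean_free)
        d_cor = compare_to_blink_free(np.mean(aff_c, axis=0), mean_free)
        improved.append(d_cor < d_unc)
        distances.append((d_unc, d_cor))
    return {
        "fraction_improved": float(np.mean(improved)),
        "n_runs": n_runs,
        "distances": distances,
    }


def confound_prediction(
    seed: int = 0,
    duration: float = 4000.0,
    rate: float = 50.0,
    amplitude: float = 0.10,
) -> dict:
    """Closed-form confound prediction vs the trial-averaged simulation.

    Simulates a long single-condition oddball-style run, averages the
    noiseless signal composition (cognitive + blink response) across trials
    after per-trial baselining, and compares it with the convolution of the
    empirical blink-offset rate with the true kernel.  Returns the fraction
    of grid points where the two agree within 2 SEM.
    """
    cfg = oddball_config(duration=duration, rate=rate, seed=seed,
                         amplitudes={"only": amplitude})
    trace, events, blinks, truth = synthesize_trace(cfg)
    n_grid = int(cfg.trial_length * cfg.rate)
    signal_only = truth.pr + truth.bpr_total
    courses = signal_only[: cfg.n_trials * n_grid].reshape(cfg.n_trials, n_grid)
    courses = courses - courses[:, [0]]
    mean = courses.mean(axis=0)
    sem = courses.std(axis=0, ddof=1) / np.sqrt(cfg.n_trials)
    emp_rate = blink_rate_timecourse(blinks, events, cfg.rate)
    kernel = gamma_kernel(cfg.true_shape, np.arange(int(3 * cfg.rate)) / cfg.rate)
    pred = predict_confound(
        emp_rate, kernel, cfg.conditions[0].cognitive_profile, 1, cfg.rate
    )
    within = np.abs(pred - mean) <= 2 * sem + 1e-3
    return {
        "fraction_within_2sem": float(within.mean()),
        "max_abs_deviation": float(np.max(np.abs(pred - mean))),
        "n_trials": cfg.n_trials,
    }


def sequence_confound_signs(
    n_seeds: int = 20,
    seed: int = 0,
    duration: float = 1200.0,
    rate: float = 50.0,
) -> dict:
    """Directional blink-history effects on baselined trial averages.

    For each seed, trials are grouped by their 4-trial blink history.  The
    blink-in-current-trial group ([0 0 0 1]) should lie below the fully
    blink-free group ([0 0 0 0]) in the trial's second half (the fresh
    constriction), and the blink-in-previous-trial group ([0 0 1 0]) above
    it in the first half (re-dilation from a spuriously low baseline).
    Returns how many seeds show each effect.
    """
    late_below = 0
    early_above = 0
    used = 0
    for k in range(n_seeds):
        cfg = oddball_config(duration=duration, rate=rate,
                             seed=(seed * 7919 + k) % (2**31),
                             amplitudes={"only": 0.10})
        trace, events, blinks, truth = synthesize_trace(cfg)
        n_grid = int(cfg.trial_length * cfg.rate)
        sig = trace.pupil - truth.baseline
        courses = sig[: cfg.n_trials * n_grid].reshape(cfg.n_trials, n_grid)
        courses = courses - courses[:, [0]]
        groups = {}
        for name, pattern in (("0001", [0, 0, 0, 1]),
                              ("0010", [0, 0, 1, 0]),
                              ("0000", [0, 0, 0, 0])):
            idx = select_trial_sequences(blinks, events, pattern)
            groups[name] = courses[idx].mean(axis=0) if len(idx) else None
        if any(v is None for v in groups.values()):
            continue
        used += 1
        half = n_grid // 2
        if groups["0001"][half:].mean() < groups["0000"][half:].mean():
            late_below += 1
        if groups["0010"][:half].mean() > groups["0000"][:half].mean():
            early_above += 1
    return {
        "n_seeds_used": used,
        "late_suppression_count": late_below,
        "early_inflation_count": early_above,
    }


def _fit_and_correct(cfg):
    """Simulate one confounded run; return traces, tables and magnitudes input."""
    trace, events, blinks_true, truth = synthesize_trace(cfg)
    filt, blinks = preprocess_trace(trace)
    model = fit_bpr_model(filt, blinks, FitConfig(seed=cfg.seed))
    corrected = subtract_bpr(filt, blinks, model).corrected
    interp = interpolate_blinks(filt, blinks).corrected
    return trace, events, truth, filt, corrected, interp


def _condition_diff(records, lo="low", hi="high"):
    mags = {}
    for r in records:
        mags.setdefault(r.condition, []).append(r.magnitude)
    return float(np.mean(mags[hi]) - np.mean(mags[lo]))


def comparator_bias(
    seed: int = 0,
    duration: float = 3600.0,
    rate: float = 40.0,
    window: tuple = (4.5, 6.0),
) -> dict:
    """Condition-difference recovery under a blink-rate-coupled design.

    Simulates a memory-load style run in which both the retrieval-locked
    response amplitude and the blink rate depend on load (the confounded
    design), applies the model-based and interpolation corrections, and
    compares the highest-minus-lowest load difference in window-averaged
    response magnitudes against the ground-truth difference computed from
    the pure cognitive component.
    """
    cfg = load_config(duration=duration, rate=rate, seed=seed)
    trace, events, truth, filt, corrected, interp = _fit_and_correct(cfg)

    win = {"fixed": window}
    diffs = {}
    for name, tr in (("uncorrected", filt), ("model", corrected),
                     ("interpolated", interp)):
        recs = response_magnitudes(events, tr, window=win)
        diffs[name] = _condition_diff(recs, lo="load1", hi="load8")
    # ground truth from the pure cognitive component (no noise, no blinks)
    pr_trace = filt.copy()
    pr_trace.pupil = truth.pr.copy()
    truth_recs = response_magnitudes(events, pr_trace, window=win)
    diffs["truth"] = _condition_diff(truth_recs, lo="load1", hi="load8")
    return diffs


def power_comparison(
    seed: int = 0,
    duration: float = 3600.0,
    rate: float = 40.0,
    reps: int = 1000,
    n_grid: tuple = (10, 20, 40, 80, 160, 320),
    alpha: float = 0.01,
    target_frac: float = 0.95,
    window: tuple = (4.5, 6.0),
) -> dict:
    """Trials-to-95%-rejection for each correction method.

    Runs the confounded memory-load design, z-scores per run, computes
    trial magnitudes, and bootstraps the slope test on the coded load at
    each sample size.  Returns min-n per method (None when the target
    fraction is not reached on the grid).
    """
    cfg = load_config(duration=duration, rate=rate, seed=seed)
    trace, events, truth, filt, corrected, interp = _fit_and_correct(cfg)
    coding = {"load1": 1.0, "load2": 2.0, "load4": 3.0, "load8": 4.0}
    out = {}
    rng = np.random.default_rng(seed % (2**31))
    for name, tr in (("uncorrected", filt), ("model", corrected),
                     ("interpolated", interp)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            recs = response_magnitudes(events, tr, window={"fixed": window},
                                       normalization="zscore")
        res = power_bootstrap(recs, coding, n_grid=list(n_grid), reps=reps,
                              alpha=alpha, target_frac=target_frac, seed=rng)
        out[name] = res
    return out
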