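"""Synthetic confounded pupillometry experiments, and the closed-form
confound predictor.

The simulator composes a pupil trace forward from the generative model:

* spontaneous fluctuation — an AR(1) Gaussian process on the 5-Hz analysis
  grid (matching the model's noise parameters), mapped through the inverse
  box-cox transform, cubic-upsampled to the native rate and centred;
* cognitive response — a per-condition event-locked profile repeated every
  trial;
* blink response — one kernel per blink, scaled by a per-blink amplitude
  drawn from a heavy-right-tailed distribution (the blink-to-blink spread
  of real responses covers nearly an order of magnitude);
* blinks — an inhomogeneous Poisson point process thinned against a
  per-trial, condition-dependent rate profile with an absolute refractory
  period (blinks concentrate at implicit task breakpoints, e.g. just after
  a response, and are suppressed during stimulus presentation).

Blink gaps are also stamped into the trace as missing samples so the
detection/cleaning path is exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.interpolate import CubicSpline

from .model import BPRShape, NoiseModel, boxcox_transform, gamma_kernel
from .preprocess import BlinkTable
from .signal_io import EventTable, PupilTrace

__all__ = [
    "ThetaDist",
    "Condition",
    "SimConfig",
    "SimGroundTruth",
    "canonical_shape",
    "fixation_config",
    "oddball_config",
    "sample_blink_trains",
    "synthesize_trace",
    "predict_confound",
    "select_trial_sequences",
]


def canonical_shape(
    trough: float = -0.2,
    t_trough: float = 0.9,
    t_shift: float = 0.3,
    alpha: float = 4.0,
) -> BPRShape:
    """Kernel with a given trough depth (mm) and time (s post blink offset).

    Defaults give the canonical blink response: constriction beginning
    ~0.3 s after the blink offset, trough of -0.2 mm at 0.9 s, recovery by
    3 s.
    """
    beta = (t_trough - t_shift) / (alpha - 1.0)
    mode_pdf = stats.gamma.pdf((alpha - 1.0) * beta, a=alpha, scale=beta)
    return BPRShape(alpha=alpha, beta=beta, gamma_amp=trough / mode_pdf, t_shift=t_shift)


@dataclass
class ThetaDist:
    """Per-blink amplitude distribution (mean 1 keeps the kernel's scale)."""

    family: str = "gamma"   # gamma | lognormal | constant
    mean: float = 1.0
    cv: float = 0.6

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.family == "constant" or self.cv == 0:
            return np.full(n, self.mean)
        if self.family == "gamma":
            k = 1.0 / self.cv**2
            return rng.gamma(shape=k, scale=self.mean / k, size=n)
        if self.family == "lognormal":
            s2 = np.log1p(self.cv**2)
            return rng.lognormal(np.log(self.mean) - s2 / 2, np.sqrt(s2), size=n)
        raise ValueError(f"unknown theta family {self.family!r}")


@dataclass
class Condition:
    """One experimental condition: event-locked response and blink-rate profile.

    Both profiles are vectors over the within-trial grid at the native rate
    (length ``trial_length * rate``); the cognitive profile is in mm, the
    blink-rate profile in Hz.
    """

    label: str
    cognitive_profile: np.ndarray
    blink_rate_profile: np.ndarray

    def __post_init__(self) -> None:
        self.cognitive_profile = np.asarray(self.cognitive_profile, dtype=float)
        self.blink_rate_profile = np.asarray(self.blink_rate_profile, dtype=float)
        if np.any(self.blink_rate_profile < 0):
            raise ValueError("blink rate profile must be >= 0")
        if self.cognitive_profile.shape != self.blink_rate_profile.shape:
            raise ValueError("condition profiles must share the trial grid")


@dataclass
class SimConfig:
    """Configuration of one synthetic run."""

    duration: float = 140.0     # s; a typical eye-tracking run
    rate: float = 500.0         # Hz native sampling
    trial_length: float = 2.0   # s
    conditions: list = field(default_factory=list)
    refractory: float = 0.2     # s; absolute refractory between blinks
    theta_dist: ThetaDist = field(default_factory=ThetaDist)
    true_shape: BPRShape = field(default_factory=canonical_shape)
    true_noise: NoiseModel = field(default_factory=NoiseModel)
    baseline: float = 3.0       # mm; mean pupil diameter
    blink_duration_range: tuple = (0.1, 0.4)  # s, uniform
    seed: int = 0

    def __post_init__(self) -> None:
        n_grid = int(round(self.trial_length * self.rate))
        for cond in self.conditions:
            if len(cond.cognitive_profile) != n_grid:
                raise ValueError(
                    f"condition {cond.label!r}: profile length "
                    f"{len(cond.cognitive_profile)} != trial grid {n_grid}"
                )

    @property
    def n_trials(self) -> int:
        return int(self.duration // self.trial_length)


@dataclass
class SimGroundTruth:
    """Simulator components; pupil == baseline + sf + pr + bpr_total."""

    sf: np.ndarray
    pr: np.ndarray
    bpr_total: np.ndarray
    blink_onsets: np.ndarray
    blink_offsets: np.ndarray
    theta: np.ndarray
    condition: np.ndarray
    baseline: float


def fixation_config(
    duration: float = 140.0,
    rate: float = 500.0,
    blink_rate: float = 0.28,
    **kwargs,
) -> SimConfig:
    """Fixation-style run: no cognitive response, constant blink rate.

    The 0.28 Hz default is a typical spontaneous blink rate during quiet
    fixation.
    """
    trial_length = kwargs.pop("trial_length", 2.0)
    n_grid = int(round(trial_length * rate))
    cond = Condition(
        label="fixation",
        cognitive_profile=np.zeros(n_grid),
        blink_rate_profile=np.full(n_grid, blink_rate),
    )
    return SimConfig(
        duration=duration, rate=rate, trial_length=trial_length,
        conditions=[cond], **kwargs,
    )


def oddball_config(
    duration: float = 140.0,
    rate: float = 500.0,
    trial_length: float = 2.0,
    amplitudes: dict | None = None,
    base_rate: float = 0.25,
    bump_rate: float = 1.0,
    rate_coupling: dict | None = None,
    **kwargs,
) -> SimConfig:
    """Oddball-style run: 2-s trials, blink-rate bump after the stimulus.

    Each condition has an event-locked dilation (half-sine over the trial,
    amplitude per condition, in mm) and a blink-rate profile suppressed
    during the 0-0.5 s stimulus period with a bump at 0.5-1 s — the
    implicit-breakpoint pattern that couples blink rate to task structure
    (overall mean rate ~0.38 Hz, a typical task blink rate).
    ``rate_coupling`` maps condition label to a multiplier on the bump,
    making the blink rate itself condition-dependent (the confounded
    design: e.g. higher memory load, more blinking).
    """
    amplitudes = amplitudes or {"low": 0.05, "mid": 0.10, "high": 0.15}
    n_grid = int(round(trial_length * rate))
    t = np.arange(n_grid) / rate
    conditions = []
    for label, amp in amplitudes.items():
        coupling = 1.0 if rate_coupling is None else rate_coupling[label]
        rate_profile = np.full(n_grid, base_rate)
        rate_profile[t < 0.5] = 0.05 * base_rate
        bump = (t >= 0.5) & (t < 1.0)
        rate_profile[bump] = bump_rate * coupling
        conditions.append(
            Condition(
                label=label,
                cognitive_profile=amp * np.sin(np.pi * t / trial_length),
                blink_rate_profile=rate_profile,
            )
        )
    return SimConfig(
        duration=duration, rate=rate, trial_length=trial_length,
        conditions=conditions, **kwargs,
    )


def load_config(
    duration: float = 2400.0,
    rate: float = 500.0,
    trial_length: float = 7.5,
    amplitudes: dict | None = None,
    rate_coupling: dict | None = None,
    base_rate: float = 0.15,
    prep_bump: float = 0.6,
    retrieval_bump: float = 0.5,
    **kwargs,
) -> SimConfig:
    """Working-memory-load style run: long trials, load-coupled blink rate.

    Each 7.5-s trial has a preparation epoch (0-1 s), stimulus (1-3 s),
    mask (3-4 s) and retrieval epoch (4-6.5 s).  The cognitive response is
    a retrieval-locked dilation whose amplitude grows with load; the blink
    rate has bumps in the preparation epoch and at retrieval onset whose
    height also grows with load — the confounded design where blink rate
    counteracts the pupil effect of interest.
    """
    amplitudes = amplitudes or {"load1": 0.05, "load2": 0.08,
                                "load4": 0.12, "load8": 0.16}
    rate_coupling = rate_coupling or {"load1": 0.6, "load2": 0.8,
                                      "load4": 1.2, "load8": 1.4}
    n_grid = int(round(trial_length * rate))
    t = np.arange(n_grid) / rate
    conditions = []
    for label, amp in amplitudes.items():
        c = rate_coupling[label]
        profile = np.full(n_grid, base_rate)
        profile[(t >= 1.0) & (t < 3.0)] = 0.3 * base_rate  # stimulus suppression
        profile[t < 1.0] = prep_bump * c
        profile[(t >= 4.0) & (t < 5.0)] = retrieval_bump * c
        cognitive = amp * np.exp(-0.5 * ((t - 5.0) / 1.0) ** 2)
        conditions.append(
            Condition(label=label, cognitive_profile=cognitive,
                      blink_rate_profile=profile)
        )
    return SimConfig(
        duration=duration, rate=rate, trial_length=trial_length,
        conditions=conditions, **kwargs,
    )


def _assign_conditions(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Balanced random condition sequence across trials."""
    labels = [c.label for c in config.conditions]
    n = config.n_trials
    seq = np.array((labels * (n // len(labels) + 1))[:n], dtype=object)
    rng.shuffle(seq)
    return seq


def _rate_function(config: SimConfig, condition_seq: np.ndarray) -> np.ndarray:
    """Blink rate (Hz) at every native sample of the run."""
    n_samples = int(round(config.duration * config.rate))
    out = np.zeros(n_samples)
    by_label = {c.label: c.blink_rate_profile for c in config.conditions}
    n_grid = int(round(config.trial_length * config.rate))
    for i, label in enumerate(condition_seq):
        a = i * n_grid
        out[a : a + n_grid] = by_label[label][: max(0, min(n_grid, n_samples - a))]
    return out


def sample_blink_trains(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    condition_seq: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample blink (onset, offset) times for one run.

    Inhomogeneous Poisson thinning against the tiled per-trial rate
    profile, with an absolute refractory after each blink offset.  Blink
    durations are uniform over ``blink_duration_range``.
    """
    rng = rng or np.random.default_rng(config.seed)
    if condition_seq is None:
        condition_seq = _assign_conditions(config, rng)
    rate_fn = _rate_function(config, condition_seq)
    rate_max = float(rate_fn.max())
    onsets, offsets = [], []
    if rate_max <= 0:
        return np.array([]), np.array([])
    t = 0.0
    last_offset = -np.inf
    dmin, dmax = config.blink_duration_range
    while True:
        t += rng.exponential(1.0 / rate_max)
        if t >= config.duration:
            break
        idx = int(t * config.rate)
        if rng.uniform() >= rate_fn[idx] / rate_max:
            continue
        if t < last_offset + config.refractory:
            continue
        dur = rng.uniform(dmin, dmax)
        if t + dur >= config.duration:
            break
        onsets.append(t)
        offsets.append(t + dur)
        last_offset = t + dur
    return np.array(onsets), np.array(offsets)


def synthesize_trace(
    config: SimConfig,
) -> tuple[PupilTrace, EventTable, BlinkTable, SimGroundTruth]:
    """Generate one synthetic run with its full ground-truth decomposition."""
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.rate))
    time = np.arange(n_samples) / config.rate

    condition_seq = _assign_conditions(config, rng)
    onsets, offsets = sample_blink_trains(config, rng, condition_seq)

    # spontaneous fluctuation: AR(1) on the 5-Hz grid, inverse-transformed,
    # cubic-upsampled, centred
    noise = config.true_noise
    coarse_dt = 0.2
    n_coarse = int(np.ceil(config.duration / coarse_dt)) + 2
    z = np.empty(n_coarse)
    z[0] = rng.normal(0, noise.sigma)
    innov = rng.normal(0, noise.sigma * np.sqrt(1 - noise.rho**2), size=n_coarse - 1)
    for i in range(1, n_coarse):
        z[i] = noise.rho * z[i - 1] + innov[i - 1]
    # keep the inverse transform in range for any lambda
    coarse_vals = boxcox_transform(z + boxcox_transform(np.array([1.0]), noise, "forward"),
                                   noise, "inverse")
    coarse_t = np.arange(n_coarse) * coarse_dt
    sf = CubicSpline(coarse_t, coarse_vals)(time)
    sf = sf - sf.mean()

    # cognitive response tiled per trial
    pr = np.zeros(n_samples)
    by_label = {c.label: c.cognitive_profile for c in config.conditions}
    n_grid = int(round(config.trial_length * config.rate))
    for i, label in enumerate(condition_seq):
        a = i * n_grid
        b = min(a + n_grid, n_samples)
        pr[a:b] = by_label[label][: b - a]

    # blink responses
    theta = config.theta_dist.sample(len(onsets), rng)
    bpr = np.zeros(n_samples)
    for j in range(len(onsets)):
        i0 = int(np.ceil(offsets[j] * config.rate))
        i1 = min(int(np.floor((offsets[j] + 3.0) * config.rate)) + 1, n_samples)
        rel = time[i0:i1] - offsets[j]
        bpr[i0:i1] += theta[j] * gamma_kernel(config.true_shape, rel)

    pupil = config.baseline + sf + pr + bpr
    valid = np.ones(n_samples, dtype=bool)
    for j in range(len(onsets)):
        a = int(np.ceil(onsets[j] * config.rate))
        b = min(int(np.floor(offsets[j] * config.rate)) + 1, n_samples)
        valid[a:b] = False

    trace = PupilTrace(
        time=time, pupil=pupil, rate=config.rate, unit="mm", valid=valid,
        run_id=f"sim-seed{config.seed}",
    )
    trial_onsets = np.arange(config.n_trials) * config.trial_length
    events = EventTable(
        onset=trial_onsets,
        duration=np.full(config.n_trials, config.trial_length),
        condition=condition_seq,
    )
    blinks = BlinkTable(onset=onsets, offset=offsets)
    truth = SimGroundTruth(
        sf=sf, pr=pr, bpr_total=bpr,
        blink_onsets=onsets, blink_offsets=offsets,
        theta=theta, condition=condition_seq, baseline=config.baseline,
    )
    return trace, events, blinks, truth


def predict_confound(
    blink_rate: np.ndarray,
    kernel: np.ndarray,
    cognitive: np.ndarray,
    n_trials_span: int,
    rate: float,
) -> np.ndarray:
    """Closed-form expected trial time course under a blink-rate profile.

    The expected blink-response component is the linear convolution of the
    tiled blink-rate profile (Hz) with the kernel sampled at the same rate
    (scaled by the sample interval), carried across trial boundaries from a
    steady-state past; the cognitive profile is tiled on top.  The result is
    re-baselined to zero at each trial onset and returned over
    ``n_trials_span`` trials.
    """
    blink_rate = np.asarray(blink_rate, dtype=float)
    cognitive = np.asarray(cognitive, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if blink_rate.shape != cognitive.shape:
        raise ValueError("blink_rate and cognitive must share the trial grid")
    n_grid = len(blink_rate)
    trial_length = n_grid / rate
    warmup = int(np.ceil(len(kernel) / n_grid)) + 1
    tiled_rate = np.tile(blink_rate, warmup + n_trials_span)
    dt = 1.0 / rate
    conv = np.convolve(tiled_rate, kernel)[: len(tiled_rate)] * dt
    span = conv[warmup * n_grid :] + np.tile(cognitive, n_trials_span)
    out = span.copy()
    for i in range(n_trials_span):
        a = i * n_grid
        out[a : a + n_grid] -= out[a]
    return out


def select_trial_sequences(
    blinks: BlinkTable,
    trials: EventTable,
    pattern,
) -> np.ndarray:
    """Indices of trials whose 4-trial blink history matches ``pattern``.

    ``pattern`` is a binary vector over trials [t-3, t-2, t-1, t]; a trial
    counts as blink-containing when any blink onset falls within its span.
    Trials with fewer than 3 preceding trials are skipped.
    """
    pattern = np.asarray(pattern, dtype=int)
    if pattern.shape != (4,):
        raise ValueError("pattern must cover 4 trials [t-3 .. t]")
    onsets = blinks.onset
    has_blink = np.array([
        bool(np.any((onsets >= trials.onset[i]) & (onsets < trials.onset[i] + trials.duration[i])))
        for i in range(len(trials))
    ], dtype=int)
    matches = [
        i for i in range(3, len(trials))
        if np.array_equal(has_blink[i - 3 : i + 1], pattern)
    ]
    return np.array(matches, dtype=int)
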