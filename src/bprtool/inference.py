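"""Staged maximum-likelihood estimation of the generative-model parameters.

Fitting proceeds in stages for one run (one subject, one lighting
condition):

1. ``lambda`` (and the positivity shift) of the box-cox transform, by
   profile likelihood on the pooled blink-free segment values;
2. the mean profiles ``mu_free`` (pointwise mean of the transformed
   blink-free segments) and ``mu_affected`` (natural cubic spline through
   the end anchors of the transformed blink-affected mean — the interior of
   the affected mean is dominated by the blink response itself, so only the
   uncontaminated ends constrain the background profile);
3. ``sigma, rho`` of the AR(1) noise covariance, by maximizing the summed
   MVN log-likelihood of the transformed blink-free segments;
4. the kernel parameters ``alpha, beta, gamma_amp, t_shift`` by maximizing
   the likelihood of the transformed (mean affected segment minus kernel)
   under ``MVN(mu_affected, Sigma / n_affected)``, with multi-start;
5. one amplitude ``theta_j`` per blink, by a bounded 1-D search each.

When two blinks fall within 3 s of each other their windows overlap; the
reference profile used for those amplitudes is the padded-and-averaged
``mu_affected`` (the interfering blink's footprint is masked and padded with
the nearest unmasked value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import CubicSpline

from .model import (
    BlinkAmplitudes,
    BPRShape,
    MeanProfiles,
    N_GRID,
    NoiseModel,
    SEGMENT_GRID,
    ar1_covariance,
    boxcox_transform,
    choose_boxcox_shift,
    gamma_kernel,
    mvn_loglik,
)
from .preprocess import BlinkTable
from .signal_io import PupilTrace

__all__ = [
    "FitConfig",
    "FittedModel",
    "InsufficientDataError",
    "estimate_lambda",
    "estimate_ar1_noise",
    "compute_mean_profiles",
    "estimate_bpr_shape",
    "estimate_blink_amplitudes",
    "fit_bpr_model",
]

_BIG = 1e12


class InsufficientDataError(ValueError):
    """Raised when a stage has too few segments to be estimated."""


@dataclass
class FitConfig:
    """Optimizer settings and parameter bounds for model fitting."""

    tol: float = 1e-8
    max_iter: int = 2000
    n_starts: int = 8               # multi-start count for the kernel fit
    alpha_bounds: tuple = (1.01, 50.0)
    beta_bounds: tuple = (0.01, 2.0)       # s
    t_shift_bounds: tuple = (-1.5, 1.5)    # s
    gamma_bounds: tuple = (-5.0, 5.0)      # mm
    sigma_bounds: tuple = (1e-6, 5.0)
    rho_bounds: tuple = (-0.99, 0.99)
    theta_bounds: tuple = (-2.0, 10.0)
    lambda_bounds: tuple = (-2.0, 3.0)
    min_affected: int = 10          # segment floor for the kernel fit
    fallback_shape: BPRShape | None = None  # used below the floor
    n_anchor: int = 2               # end anchors for the mu_affected spline
    theta_overlap_sweeps: int = 2   # conditioning rounds for overlapping blinks
    seed: int = 0                   # multi-start jitter seed

    def __post_init__(self) -> None:
        for name in ("alpha_bounds", "beta_bounds", "t_shift_bounds",
                     "gamma_bounds", "sigma_bounds", "rho_bounds",
                     "theta_bounds", "lambda_bounds"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be well-ordered")


@dataclass
class FittedModel:
    """Full parameter set fitted to one run, plus per-stage diagnostics."""

    shape: BPRShape | None
    noise: NoiseModel
    means: MeanProfiles
    amplitudes: BlinkAmplitudes
    blink_index: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_free(self) -> int:
        return int(self.diagnostics.get("n_free", 0))

    @property
    def n_affected(self) -> int:
        return int(self.diagnostics.get("n_affected", len(self.amplitudes)))


def _as_matrix(segments) -> np.ndarray:
    mat = np.asarray(segments, dtype=float)
    if mat.ndim == 1:
        mat = mat[None, :]
    if mat.shape[-1] != N_GRID:
        raise ValueError(f"segments must have length {N_GRID}")
    return mat


def estimate_lambda(
    free_segments,
    config: FitConfig | None = None,
    shift: float | None = None,
) -> tuple[float, float]:
    """Box-cox exponent and positivity shift from pooled blink-free values.

    The shift is ``max(0, 0.01 - min(values))`` (band-passed segments are
    near zero-mean, and the classic transform needs positive data); lambda
    maximizes the profile box-cox log-likelihood of the pooled, shifted
    values and is clamped to the configured bounds.  Callers that must also
    transform deeper-reaching data (the blink-affected troughs) can pass a
    larger ``shift`` computed over the full run.
    """
    config = config or FitConfig()
    mat = _as_matrix(free_segments)
    if mat.shape[0] < 2:
        raise InsufficientDataError("need at least 2 blink-free segments")
    # sorted for permutation-invariant float accumulation
    pooled = np.sort(mat.ravel())
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate input: all segment values are constant")
    if shift is None:
        shift = choose_boxcox_shift(pooled)
    lo, hi = config.lambda_bounds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lam = float(
            optimize.minimize_scalar(
                lambda l: -_boxcox_llf(l, pooled + shift),
                bounds=(lo, hi),
                method="bounded",
            ).x
        )
    return float(np.clip(lam, lo, hi)), shift


def _boxcox_llf(lam: float, x: np.ndarray) -> float:
    return float(stats.boxcox_llf(lam, x))


def _ar1_suffstats(transformed: np.ndarray, mu: np.ndarray):
    resid = transformed - mu
    n_seg, n = resid.shape
    # sufficient statistics for the tridiagonal AR(1) inverse; sorted sums
    # keep the estimates exactly invariant to segment order
    sq = resid**2
    d_ends = float(np.sum(np.sort(np.concatenate([sq[:, 0], sq[:, -1]]))))
    d_interior = float(np.sum(np.sort(sq[:, 1:-1].ravel())))
    off1 = float(np.sum(np.sort((resid[:, :-1] * resid[:, 1:]).ravel())))
    return n_seg, n, d_ends, d_interior, off1


def _ar1_negloglik(params, suff):
    sigma, rho = params
    n_seg, n, d_ends, d_interior, off1 = suff
    if sigma <= 0 or not -1 < rho < 1:
        return _BIG
    one_m = 1.0 - rho**2
    quad = (d_ends + (1.0 + rho**2) * d_interior - 2.0 * rho * off1) / one_m
    logdet = n * 2.0 * np.log(sigma) + (n - 1) * np.log(one_m)
    ll = -0.5 * (n_seg * n * np.log(2 * np.pi) + n_seg * logdet + quad / sigma**2)
    return -ll


def estimate_ar1_noise(
    free_segments,
    noise: NoiseModel,
    mu_free: np.ndarray,
    config: FitConfig | None = None,
) -> tuple[float, float, bool]:
    """MLE of (sigma, rho) from transformed blink-free segments.

    Maximizes the summed MVN log-likelihood with mean ``mu_free`` and AR(1)
    covariance, by bounded optimization initialized at the sample SD and
    lag-1 autocorrelation of the residuals.  Returns (sigma, rho,
    converged); a single segment still yields an estimate, flagged.
    """
    config = config or FitConfig()
    mat = _as_matrix(free_segments)
    if mat.shape[0] == 0:
        raise InsufficientDataError("need at least 1 blink-free segment")
    transformed = boxcox_transform(mat, noise, "forward")
    mu_free = np.asarray(mu_free, dtype=float)
    suff = _ar1_suffstats(transformed, mu_free)

    resid = transformed - mu_free
    sd0 = float(np.std(resid))
    if sd0 == 0:
        sd0 = 1e-3
    flat = resid
    num = float(np.sum(flat[:, :-1] * flat[:, 1:]))
    den = float(np.sum(flat**2))
    rho0 = num / den if den > 0 else 0.0
    rho0 = float(np.clip(rho0, config.rho_bounds[0] + 1e-3, config.rho_bounds[1] - 1e-3))

    res = optimize.minimize(
        _ar1_negloglik,
        x0=[sd0, rho0],
        args=(suff,),
        method="L-BFGS-B",
        bounds=[config.sigma_bounds, config.rho_bounds],
        options={"maxiter": config.max_iter, "ftol": config.tol},
    )
    sigma, rho = res.x
    converged = bool(res.success) and mat.shape[0] > 1
    return float(sigma), float(rho), converged


def compute_mean_profiles(
    free_segments,
    affected_segments,
    noise: NoiseModel,
    n_anchor: int = 2,
) -> MeanProfiles:
    """Mean background profiles in transformed space.

    ``mu_free`` is the pointwise mean of the transformed blink-free
    segments.  ``mu_affected`` is a natural cubic spline through the first
    and last ``n_anchor`` grid points of the transformed blink-affected
    mean, evaluated on the full 16-point grid: the interior of the affected
    mean carries the blink response itself and must not constrain the
    background.
    """
    free = _as_matrix(free_segments)
    affected = _as_matrix(affected_segments)
    if free.shape[0] == 0 or affected.shape[0] == 0:
        raise InsufficientDataError("need at least one segment of each kind")
    mu_free = np.sort(boxcox_transform(free, noise, "forward"), axis=0).mean(axis=0)
    aff_mean = np.sort(boxcox_transform(affected, noise, "forward"), axis=0).mean(axis=0)
    anchor_idx = np.r_[np.arange(n_anchor), np.arange(N_GRID - n_anchor, N_GRID)]
    spline = CubicSpline(
        SEGMENT_GRID[anchor_idx], aff_mean[anchor_idx], bc_type="natural"
    )
    mu_affected = spline(SEGMENT_GRID)
    return MeanProfiles(mu_free=mu_free, mu_affected=mu_affected)


def _shape_negloglik(params, mean_raw, noise, mu_affected, cov_scaled):
    alpha, beta, gamma_amp, t_shift = params
    try:
        shape = BPRShape(alpha=alpha, beta=beta, gamma_amp=gamma_amp, t_shift=t_shift)
    except ValueError:
        return _BIG
    h = gamma_kernel(shape, SEGMENT_GRID)
    shifted = mean_raw - h + noise.shift_bc
    if np.any(shifted <= 0):
        return _BIG
    resid = boxcox_transform(mean_raw - h, noise, "forward")
    return -mvn_loglik(resid, mu_affected, cov_scaled)


def estimate_bpr_shape(
    affected_segments,
    noise: NoiseModel,
    means: MeanProfiles,
    config: FitConfig | None = None,
) -> tuple[BPRShape, dict]:
    """MLE of the kernel parameters from the blink-affected mean.

    Maximizes ``MVN(g(mean(Y_affected) - h); mu_affected, Sigma/n)`` over
    (alpha, beta, gamma_amp, t_shift), multi-starting from jittered initial
    values around (t=0, time-to-trough, trough depth).
    """
    config = config or FitConfig()
    mat = _as_matrix(affected_segments)
    n_aff = mat.shape[0]
    if n_aff < config.min_affected:
        raise InsufficientDataError(
            f"{n_aff} affected segments < floor {config.min_affected}"
        )
    mean_raw = np.sort(mat, axis=0).mean(axis=0)  # order-invariant column means
    cov_scaled = ar1_covariance(noise.sigma, noise.rho) / n_aff

    # Initial values: the kernel mode is placed at the observed trough of
    # the affected mean, with the amplitude matched to the trough depth.
    # The likelihood surface has well-separated basins in (alpha, t_shift),
    # so a deterministic coarse grid over those two (with beta and gamma
    # solved from the trough) seeds the local optimizer, plus seeded jitter.
    trough_idx = int(np.argmin(mean_raw))
    t_trough = max(float(SEGMENT_GRID[trough_idx]), 0.3)
    depth = float(min(mean_raw[trough_idx], -1e-3))

    def trough_matched(alpha, t_shift):
        beta = float(np.clip((t_trough - t_shift) / (alpha - 1.0),
                             *config.beta_bounds))
        f_mode = stats.gamma.pdf((alpha - 1) * beta, a=alpha, scale=beta)
        gamma0 = float(np.clip(depth / max(f_mode, 1e-6), *config.gamma_bounds))
        return [alpha, beta, gamma0, t_shift]

    rng = np.random.default_rng(config.seed)
    grid_starts = [
        trough_matched(alpha, t_shift)
        for alpha in (1.5, 2.0, 4.0, 8.0)
        for t_shift in (0.0, 0.5 * t_trough)
        if t_shift < t_trough
    ]
    for _ in range(max(0, config.n_starts - len(grid_starts))):
        alpha = float(np.clip(2.0 * rng.lognormal(0, 0.7), *config.alpha_bounds))
        t_shift = float(np.clip(rng.uniform(0, 0.8) * t_trough,
                                *config.t_shift_bounds))
        grid_starts.append(trough_matched(alpha, min(t_shift, t_trough - 0.05)))

    args = (mean_raw, noise, means.mu_affected, cov_scaled)
    ranked = sorted(grid_starts, key=lambda x0: _shape_negloglik(x0, *args))
    bounds = [config.alpha_bounds, config.beta_bounds,
              config.gamma_bounds, config.t_shift_bounds]
    best = None
    n_refine = max(3, config.n_starts // 2)
    for x0 in ranked[:n_refine]:
        res = optimize.minimize(
            _shape_negloglik,
            x0=x0,
            args=args,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tol},
        )
        if res.fun < _BIG and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("no multi-start converged for the kernel fit")
    starts_used = ranked[:n_refine]
    alpha, beta, gamma_amp, t_shift = best.x
    shape = BPRShape(alpha=float(alpha), beta=float(beta),
                     gamma_amp=float(gamma_amp), t_shift=float(t_shift))
    diag = {
        "loglik": float(-best.fun),
        "converged": bool(best.success),
        "n_starts": config.n_starts,
        "starts": starts_used,
    }
    return shape, diag


def _theta_negloglik(theta, segment, h, noise, mu_ref, cov):
    adjusted = segment - theta * h
    if np.any(adjusted + noise.shift_bc <= 0):
        return _BIG
    resid = boxcox_transform(adjusted, noise, "forward")
    return -mvn_loglik(resid, mu_ref, cov)


def estimate_blink_amplitudes(
    affected_segments,
    shape: BPRShape,
    noise: NoiseModel,
    means: MeanProfiles,
    config: FitConfig | None = None,
    reference_profiles: np.ndarray | None = None,
) -> BlinkAmplitudes:
    """Per-blink kernel gain theta_j by bounded 1-D likelihood search.

    ``reference_profiles`` (n_segments x 16) optionally replaces
    ``mu_affected`` per segment; used for overlapping blinks where the
    neighbour's footprint is padded out of the reference.
    """
    config = config or FitConfig()
    mat = _as_matrix(affected_segments)
    h = gamma_kernel(shape, SEGMENT_GRID)
    cov = ar1_covariance(noise.sigma, noise.rho)
    thetas = np.empty(mat.shape[0])
    for j, seg in enumerate(mat):
        mu_ref = (
            means.mu_affected
            if reference_profiles is None
            else reference_profiles[j]
        )
        res = optimize.minimize_scalar(
            _theta_negloglik,
            bounds=config.theta_bounds,
            args=(seg, h, noise, mu_ref, cov),
            method="bounded",
            options={"xatol": 1e-6},
        )
        thetas[j] = res.x
    return BlinkAmplitudes(theta=thetas)


def overlap_reference(
    mu_affected: np.ndarray,
    anchor: float,
    neighbour_offsets: np.ndarray,
    window: float = 3.0,
) -> np.ndarray:
    """Reference profile for a blink whose window contains other blinks.

    For each interfering blink, the grid points inside its 3-s footprint are
    masked in a copy of ``mu_affected`` and padded with the nearest unmasked
    value toward the window edge; the padded copies are averaged.
    """
    grid_abs = anchor + SEGMENT_GRID
    copies = []
    for off in np.atleast_1d(neighbour_offsets):
        mask = (grid_abs >= off) & (grid_abs <= off + window)
        if mask.all() or not mask.any():
            copies.append(mu_affected.copy())
            continue
        padded = mu_affected.copy()
        unmasked = np.flatnonzero(~mask)
        masked = np.flatnonzero(mask)
        # pad each masked run from the window's first/last unmasked value
        first_u, last_u = unmasked[0], unmasked[-1]
        padded[masked[masked < first_u]] = mu_affected[first_u]
        padded[masked[masked > last_u]] = mu_affected[last_u]
        interior = masked[(masked > first_u) & (masked < last_u)]
        if interior.size:  # interior gap: nearest unmasked on each side
            for i in interior:
                left = unmasked[unmasked < i][-1]
                right = unmasked[unmasked > i][0]
                padded[i] = mu_affected[left] if i - left <= right - i else mu_affected[right]
        copies.append(padded)
    if not copies:
        return mu_affected.copy()
    return np.mean(copies, axis=0)


def fit_bpr_model(
    trace: PupilTrace,
    blinks: BlinkTable,
    config: FitConfig | None = None,
) -> FittedModel:
    """Fit the full generative model to one preprocessed run.

    ``trace`` must be artifact-interpolated and band-passed.  Segments are
    extracted on the 16-point grid; the stages run in order (lambda ->
    means -> sigma,rho -> kernel -> amplitudes).  Blinks with another blink
    within 3 s are marked overlapping and their amplitude reference is the
    padded-and-averaged ``mu_affected``.
    """
    from .evaluate import extract_segments  # deferred: evaluate imports model

    config = config or FitConfig()
    diagnostics: dict = {}

    if len(blinks) == 0:
        warnings.warn("run has no blinks; returning flagged empty model", stacklevel=2)
        noise = NoiseModel()
        segs = extract_segments(trace, blinks)
        free = [s.values for s in segs if s.kind == "blink_free"]
        if len(free) >= 2:
            lam, shift = estimate_lambda(free, config)
            noise = NoiseModel(lambda_bc=lam, shift_bc=shift,
                               sigma=noise.sigma, rho=noise.rho)
            mu_free = boxcox_transform(_as_matrix(free), noise, "forward").mean(axis=0)
            sigma, rho, conv = estimate_ar1_noise(free, noise, mu_free, config)
            noise = NoiseModel(lambda_bc=lam, shift_bc=shift, sigma=sigma, rho=rho)
            means = MeanProfiles(mu_free=mu_free, mu_affected=mu_free.copy())
        else:
            means = MeanProfiles(mu_free=np.zeros(N_GRID), mu_affected=np.zeros(N_GRID))
        return FittedModel(
            shape=None,
            noise=noise,
            means=means,
            amplitudes=BlinkAmplitudes(theta=np.array([])),
            diagnostics={"flag": "no_blinks", "n_free": len(free), "n_affected": 0},
        )

    segments = extract_segments(trace, blinks)
    free = [s.values for s in segments if s.kind == "blink_free"]
    affected = [s for s in segments if s.kind == "blink_affected"]
    if len(free) == 0:
        raise InsufficientDataError("no blink-free segments in this run")
    aff_mat = _as_matrix([s.values for s in affected]) if affected else np.empty((0, N_GRID))
    blink_index = np.array([s.blink_index for s in affected], dtype=int)

    # the shift must keep every transformed value positive, including the
    # blink-affected troughs, so it is chosen over the pooled run
    all_vals = np.concatenate([_as_matrix(free).ravel(), aff_mat.ravel()])
    lam, shift = estimate_lambda(free, config, shift=choose_boxcox_shift(all_vals))
    noise = NoiseModel(lambda_bc=lam, shift_bc=shift, sigma=1.0, rho=0.0)
    diagnostics["lambda"] = {"lambda_bc": lam, "shift_bc": shift, "converged": True}

    means = compute_mean_profiles(free, aff_mat, noise, n_anchor=config.n_anchor)

    sigma, rho, conv = estimate_ar1_noise(free, noise, means.mu_free, config)
    noise = NoiseModel(lambda_bc=lam, shift_bc=shift, sigma=sigma, rho=rho)
    free_ll = sum(
        mvn_loglik(
            boxcox_transform(f, noise, "forward"),
            means.mu_free,
            ar1_covariance(sigma, rho),
        )
        for f in free
    )
    diagnostics["noise"] = {
        "sigma": sigma, "rho": rho, "converged": conv, "loglik": float(free_ll),
    }

    # The kernel shape is estimated from isolated blinks when enough exist:
    # overlapping neighbours leak their own response into the affected mean
    # (including its end anchors) and bias the amplitude downward.
    iso_mat = _as_matrix(
        [s.values for s in affected if s.isolated]
    ) if any(s.isolated for s in affected) else np.empty((0, N_GRID))
    shape_mat = iso_mat if iso_mat.shape[0] >= config.min_affected else aff_mat
    shape_means = (
        compute_mean_profiles(free, shape_mat, noise, n_anchor=config.n_anchor)
        if shape_mat is iso_mat
        else means
    )
    try:
        shape, shape_diag = estimate_bpr_shape(shape_mat, noise, shape_means, config)
    except InsufficientDataError:
        if config.fallback_shape is None:
            raise
        shape = config.fallback_shape
        shape_diag = {"converged": True, "fallback": True}
    shape_diag["n_shape_segments"] = int(shape_mat.shape[0])
    shape_diag["isolated_only"] = bool(shape_mat is iso_mat)
    diagnostics["shape"] = shape_diag

    overlapping = np.array([s.overlapping for s in affected], dtype=bool)
    references = np.tile(means.mu_affected, (len(affected), 1))
    offsets = blinks.offset
    for j, seg in enumerate(affected):
        if not overlapping[j]:
            continue
        others = offsets[
            (np.abs(offsets - seg.anchor) > 1e-9)
            & (offsets > seg.anchor - 3.0)
            & (offsets < seg.anchor + 3.0)
        ]
        if others.size:
            references[j] = overlap_reference(means.mu_affected, seg.anchor, others)
    amplitudes = estimate_blink_amplitudes(
        aff_mat, shape, noise, means, config, reference_profiles=references
    )
    # Overlapping neighbours leak into each other's windows and bias the
    # single-blink amplitude search (worst at ~1-s lags).  A few rounds of
    # conditioning each blink's 1-D search on the neighbours' current
    # estimated components removes that bias while keeping the per-blink
    # search itself one-dimensional.
    anchors = np.array([s.anchor for s in affected])
    for _ in range(config.theta_overlap_sweeps if overlapping.any() else 0):
        theta = amplitudes.theta
        adjusted = aff_mat.copy()
        for j in np.flatnonzero(overlapping):
            near = np.flatnonzero(
                (np.abs(anchors - anchors[j]) > 1e-9)
                & (np.abs(anchors - anchors[j]) < 3.0)
            )
            for k in near:
                rel = SEGMENT_GRID + anchors[j] - anchors[k]
                adjusted[j] -= theta[k] * gamma_kernel(shape, rel)
        refreshed = estimate_blink_amplitudes(
            adjusted[overlapping], shape, noise, means, config
        )
        new_theta = theta.copy()
        new_theta[overlapping] = refreshed.theta
        if np.max(np.abs(new_theta - theta)) < 1e-6:
            amplitudes = BlinkAmplitudes(theta=new_theta)
            break
        amplitudes = BlinkAmplitudes(theta=new_theta)
    diagnostics["amplitudes"] = {"converged": True, "n": len(amplitudes)}
    diagnostics["n_free"] = len(free)
    diagnostics["n_affected"] = len(affected)
    diagnostics["overlapping"] = overlapping.tolist()

    return FittedModel(
        shape=shape,
        noise=noise,
        means=means,
        amplitudes=amplitudes,
        blink_index=blink_index,
        diagnostics=diagnostics,
    )
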