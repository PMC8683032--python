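"""Forward generative model of blink-locked pupillary responses.

A 3-s pupil window ``Y`` (16 samples at 5 Hz) is modelled as

* blink-free:      g(Y) ~ MVN(mu_free, Sigma)
* blink-affected:  g(Y - theta_j * h) ~ MVN(mu_affected, Sigma)

where ``g`` is a (shifted) box-cox power transform with exponent ``lambda``,
``Sigma`` is the stationary AR(1) covariance ``sigma^2 * rho^|k-l|``, and
``h`` is the blink-locked response kernel: a gamma probability density in
shape-scale form, scaled by a (typically negative) amplitude and shifted in
time so the constriction starts a few hundred ms after the blink offset.
``theta_j`` is a per-blink gain on the kernel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from scipy.linalg import solve_triangular

__all__ = [
    "BPRShape",
    "NoiseModel",
    "MeanProfiles",
    "BlinkAmplitudes",
    "SEGMENT_GRID",
    "N_GRID",
    "gamma_kernel",
    "boxcox_transform",
    "choose_boxcox_shift",
    "ar1_covariance",
    "mvn_loglik",
]

#: Analysis grid for 3-s segments: {0, 0.2, ..., 3.0} s, 16 points at 5 Hz.
SEGMENT_GRID = np.arange(16) * 0.2
N_GRID = 16

#: Positivity margin (mm) for the shifted box-cox transform of band-passed data.
BOXCOX_EPS = 0.01


@dataclass
class BPRShape:
    """Blink-locked response kernel parameters.

    ``alpha`` and ``beta`` are the gamma shape and scale (s); the kernel
    peaks (in magnitude) at ``t_shift + (alpha - 1) * beta`` seconds after
    the blink offset.  ``gamma_amp`` (mm) carries the sign: negative values
    encode the usual constriction.
    """

    alpha: float
    beta: float
    gamma_amp: float
    t_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if abs(self.t_shift) > 1.5:
            raise ValueError("|t_shift| must be <= 1.5 s")

    @property
    def time_to_peak(self) -> float:
        """Mode of the kernel in seconds after blink offset."""
        return self.t_shift + max(self.alpha - 1.0, 0.0) * self.beta


@dataclass
class NoiseModel:
    """Box-cox transform and AR(1) background-noise parameters."""

    lambda_bc: float = 1.0
    shift_bc: float = 0.0   # mm, positivity offset for band-passed data
    sigma: float = 0.05     # transformed units
    rho: float = 0.8

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("|rho| must be < 1")


@dataclass
class MeanProfiles:
    """Mean 16-point profiles of transformed blink-free/-affected segments."""

    mu_free: np.ndarray
    mu_affected: np.ndarray

    def __post_init__(self) -> None:
        self.mu_free = np.asarray(self.mu_free, dtype=float)
        self.mu_affected = np.asarray(self.mu_affected, dtype=float)
        for name, v in (("mu_free", self.mu_free), ("mu_affected", self.mu_affected)):
            if v.shape != (N_GRID,):
                raise ValueError(f"{name} must have length {N_GRID}")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")


@dataclass
class BlinkAmplitudes:
    """Per-blink kernel gains theta_j (dimensionless, typically near 1)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.size and not np.all(np.isfinite(self.theta)):
            raise ValueError("theta must be finite")

    def __len__(self) -> int:
        return len(self.theta)


def gamma_kernel(shape: BPRShape, times: np.ndarray) -> np.ndarray:
    """Evaluate the blink-locked response kernel at the given times.

    ``h(x) = gamma_amp * f(x - t_shift; alpha, beta)`` with ``f`` the gamma
    density in shape-scale form; zero for ``x <= t_shift``.
    """
    times = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(times)):
        raise ValueError("times must be finite")
    x = times - shape.t_shift
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = shape.gamma_amp * stats.gamma.pdf(x[pos], a=shape.alpha, scale=shape.beta)
    return out


def boxcox_transform(
    values: np.ndarray,
    noise: NoiseModel,
    direction: str = "forward",
) -> np.ndarray:
    """Shifted box-cox power transform (or its exact inverse).

    Forward: ``y -> ((y + shift)^lambda - 1) / lambda`` (``ln(y + shift)``
    at ``lambda = 0``).  Forward requires ``y + shift > 0`` elementwise; a
    violation signals that the shift is too small for the data.
    """
    values = np.asarray(values, dtype=float)
    lam, shift = noise.lambda_bc, noise.shift_bc
    if direction == "forward":
        shifted = values + shift
        if np.any(shifted <= 0):
            raise ValueError(
                "box-cox forward transform requires values + shift > 0 "
                f"(min shifted value {np.min(shifted):.4g})"
            )
        if abs(lam) < 1e-10:  # numerically the log branch
            return np.log(shifted)
        # expm1 form stays accurate as lambda -> 0
        return np.expm1(lam * np.log(shifted)) / lam
    if direction == "inverse":
        if abs(lam) < 1e-10:
            return np.exp(values) - shift
        base = lam * values
        if np.any(base <= -1):
            raise ValueError("inverse box-cox out of range")
        return np.exp(np.log1p(base) / lam) - shift
    raise ValueError(f"unknown direction {direction!r}")


def choose_boxcox_shift(values: np.ndarray, eps: float = BOXCOX_EPS) -> float:
    """Positivity offset for band-passed (near zero-mean) data.

    Returns ``max(0, eps - min(values))`` so the shifted data sit at least
    ``eps`` above zero.
    """
    values = np.asarray(values, dtype=float)
    return float(max(0.0, eps - np.min(values)))


def ar1_covariance(sigma: float, rho: float, n: int = N_GRID) -> np.ndarray:
    """Stationary AR(1) covariance: entry (k,l) = sigma^2 * rho^|k-l|."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not -1.0 < rho < 1.0:
        raise ValueError("|rho| must be < 1")
    k = np.arange(n)
    return sigma**2 * rho ** np.abs(k[:, None] - k[None, :])


def mvn_loglik(x: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> float:
    """Exact multivariate normal log-density via Cholesky factorization."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mu = np.atleast_1d(np.asarray(mu, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    n = x.shape[-1]
    if mu.shape[-1] != n or cov.shape != (n, n):
        raise ValueError("dimension mismatch between x, mu and cov")
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is not positive-definite"
        ) from exc
    z = solve_triangular(chol, (x - mu).T, lower=True).T
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    quad = np.sum(z**2, axis=-1)
    return float(np.sum(-0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)))


# --- serialization -----------------------------------------------------------

def model_to_dict(shape, noise, means, amplitudes, diagnostics=None) -> dict:
    """JSON-serializable dict of a fitted model (see inference.FittedModel)."""
    d = {
        "alpha": shape.alpha if shape is not None else None,
        "beta": shape.beta if shape is not None else None,
        "gamma_amp": shape.gamma_amp if shape is not None else None,
        "t_shift": shape.t_shift if shape is not None else None,
        "lambda_bc": noise.lambda_bc,
        "shift_bc": noise.shift_bc,
        "sigma": noise.sigma,
        "rho": noise.rho,
        "mu_free": means.mu_free.tolist(),
        "mu_affected": means.mu_affected.tolist(),
        "theta": amplitudes.theta.tolist(),
        "convention_tags": {
            "gamma_parameterization": "shape-scale",
            "boxcox": "two-parameter shifted",
            "kernel_sign": "amplitude carries constriction sign",
        },
    }
    if diagnostics is not None:
        d["diagnostics"] = diagnostics
    return d


def save_model(path: str | Path, shape, noise, means, amplitudes, diagnostics=None) -> None:
    with open(path, "w") as fh:
        json.dump(model_to_dict(shape, noise, means, amplitudes, diagnostics), fh, indent=2)
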