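"""Probability-distortion models: LLO, BLO, and the 18-model factorial space.

The linear-in-log-odds (LLO) model describes distorted reports of a
probability or relative frequency ``p`` as a linear transform in log-odds,

    lambda[pi(p)] = gamma * lambda[p] + (1 - gamma) * lambda[p0] + eps,

with slope ``gamma`` (inverted-S distortion for gamma < 1), crossover
``p0`` where pi(p) = p, and Gaussian noise of SD ``sigma_lambda`` on the
log-odds scale.

The bounded log-odds (BLO) model is generative: the log-odds of ``p`` is
truncated to [delta_minus, delta_plus], mapped linearly onto a bounded
Thurstone scale (slope ``eta``), and the final estimate shrinks toward an
anchor ``lambda0`` with weight omega = 1 / (1 + alpha * V(p_hat)), where
V(p_hat) = p(1-p)/ns * (N-ns)/(N-1) is the sampling variance of a
without-replacement sample of ns = b + N**a dots out of N.

The factorial model space crosses three dimensions:

* D1 scale: log-odds, Prelec (-log(-log p)) or linear;
* D2: bounded (truncation active) vs bounds-free;
* D3 variance: V(p_hat) with ns = b + N**a, V(p_hat) with constant ns,
  or constant V.

For constant-V models the shrinkage weight is not identifiable against
the scale slope and an intercept, so those models drop alpha and use
mean = Lambda + lambda0; the bounds-free log-odds cell then reduces
exactly to LLO (3 parameters including sigma_lambda) and the bounds-free
Prelec cell to the two-parameter Prelec function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np

EPS_CLIP = 1.0 / 202.0
"""Response clipping bound: half a step of a ~1%-resolution click scale."""

SCALES = ("logodds", "prelec", "linear")
VARIANCES = ("vnspow", "vnsconst", "vconst")


# ---------------------------------------------------------------- scales

def scale_transform(p, scale: str):
    """Map probability to the internal representation scale."""
    p = np.asarray(p, dtype=float)
    if scale == "logodds":
        _check_open_unit(p)
        return np.log(p / (1.0 - p))
    if scale == "prelec":
        _check_open_unit(p)
        return -np.log(-np.log(p))
    if scale == "linear":
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("p must lie in [0, 1] for the linear scale")
        return p
    raise ValueError(f"unknown scale {scale!r}")


def inverse_scale_transform(x, scale: str):
    """Inverse of :func:`scale_transform`; round-trips on (0, 1)."""
    x = np.asarray(x, dtype=float)
    if scale == "logodds":
        return 1.0 / (1.0 + np.exp(-x))
    if scale == "prelec":
        return np.exp(-np.exp(-x))
    if scale == "linear":
        return x
    raise ValueError(f"unknown scale {scale!r}")


def _check_open_unit(p):
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("p must lie strictly inside (0, 1)")


def log_odds(p):
    return scale_transform(p, "logodds")


# ------------------------------------------------------------- parameters

@dataclass
class LLOParams:
    gamma: float
    p0: float
    sigma_lambda: float

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not (0 < self.p0 < 1):
            raise ValueError("p0 must lie in (0, 1)")
        if self.sigma_lambda <= 0:
            raise ValueError("sigma_lambda must be > 0")


@dataclass
class BLOParams:
    delta_minus: float
    delta_plus: float
    a: float
    b: float
    eta: float
    lambda0: float
    alpha: float
    sigma_lambda: float

    def __post_init__(self):
        if self.delta_minus > self.delta_plus:
            raise ValueError("delta_minus must be <= delta_plus")
        if self.a < 0 or self.b < 0 or self.alpha < 0:
            raise ValueError("a, b, alpha must be >= 0")
        if self.eta <= 0 or self.sigma_lambda <= 0:
            raise ValueError("eta and sigma_lambda must be > 0")

    def as_dict(self):
        return dict(delta_minus=self.delta_minus, delta_plus=self.delta_plus,
                    a=self.a, b=self.b, eta=self.eta, lambda0=self.lambda0,
                    alpha=self.alpha, sigma_lambda=self.sigma_lambda)


# ------------------------------------------------------------- model space

@dataclass(frozen=True)
class ModelSpec:
    """A point in the D1 x D2 x D3 factorial model space."""

    scale: str
    bounded: bool
    variance: str

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.variance not in VARIANCES:
            raise ValueError(f"unknown variance {self.variance!r}")

    @property
    def key(self) -> str:
        return f"{self.scale}-{'bounded' if self.bounded else 'free'}-{self.variance}"

    @property
    def param_names(self) -> tuple:
        names = []
        if self.bounded:
            names += ["delta_minus", "delta_plus"]
        names += ["eta", "lambda0"]
        if self.variance == "vnspow":
            names += ["a", "b", "alpha"]
        elif self.variance == "vnsconst":
            names += ["ns", "alpha"]
        names += ["sigma_lambda"]
        return tuple(names)

    @property
    def n_free_params(self) -> int:
        return len(self.param_names)


MODEL_SPACE = [
    ModelSpec(scale=s, bounded=b, variance=v)
    for s, b, v in product(SCALES, (True, False), VARIANCES)
]
MODEL_REGISTRY = {m.key: m for m in MODEL_SPACE}

BLO_SPEC = MODEL_REGISTRY["logodds-bounded-vnspow"]
LLO_SPEC = MODEL_REGISTRY["logodds-free-vconst"]
PRELEC_SPEC = MODEL_REGISTRY["prelec-free-vconst"]


def get_model(key) -> ModelSpec:
    if isinstance(key, ModelSpec):
        return key
    try:
        return MODEL_REGISTRY[key]
    except KeyError:
        raise KeyError(f"unknown model key {key!r}; known: {sorted(MODEL_REGISTRY)}")


# -------------------------------------------------------- sampling variance

def sampling_variance(p, N, a=None, b=None, ns=None, variance: str = "vnspow"):
    """Variance of the estimate from sampling ns of N dots without replacement.

    V = p(1-p)/ns * (N-ns)/(N-1), clamped at zero (ns may exceed N).  For
    ``vnspow`` the sample size is ns = b + N**a; for ``vnsconst`` it is the
    free constant ``ns``; for ``vconst`` the variance is the constant 1.
    N = 1 yields V = 0 (degenerate denominator).
    """
    p = np.asarray(p, dtype=float)
    N = np.asarray(N, dtype=float)
    if np.any(N < 1):
        raise ValueError("N must be >= 1")
    if variance == "vconst":
        return np.ones(np.broadcast(p, N).shape)
    if variance == "vnspow":
        ns_eff = b + N ** a
    elif variance == "vnsconst":
        ns_eff = np.broadcast_to(float(ns), np.broadcast(p, N).shape)
    else:
        raise ValueError(f"unknown variance {variance!r}")
    denom = np.where(N > 1, N - 1.0, 1.0)
    V = p * (1.0 - p) / ns_eff * (N - ns_eff) / denom
    V = np.where(N > 1, V, 0.0)
    return np.maximum(V, 0.0)


# ------------------------------------------------------------ forward models

def transformed_mean(p, N, spec: ModelSpec, params: dict):
    """Mean reported value on the model's transformed scale."""
    s = scale_transform(p, spec.scale)
    if spec.bounded:
        dm, dp = params["delta_minus"], params["delta_plus"]
        if dm > dp:
            raise ValueError("delta_minus must be <= delta_plus")
        lam = params["eta"] * (np.clip(s, dm, dp) - 0.5 * (dm + dp))
    else:
        lam = params["eta"] * s
    if spec.variance == "vconst":
        mean = lam + params["lambda0"]
    else:
        V = sampling_variance(p, N, a=params.get("a"), b=params.get("b"),
                              ns=params.get("ns"), variance=spec.variance)
        omega = 1.0 / (1.0 + params["alpha"] * V)
        mean = omega * lam + (1.0 - omega) * params["lambda0"]
    if not np.all(np.isfinite(mean)):
        raise ValueError("non-finite model mean; check parameters")
    return mean


def model_median(p, N, spec: ModelSpec, params: dict):
    """Median reported proportion (inverse transform of the mean)."""
    return inverse_scale_transform(transformed_mean(p, N, spec, params), spec.scale)


def model_sample(p, N, spec: ModelSpec, params: dict, rng):
    """Sample reported proportions: Gaussian noise on the transformed scale."""
    mean = transformed_mean(p, N, spec, params)
    x = mean + params["sigma_lambda"] * rng.standard_normal(np.shape(mean))
    if spec.scale == "linear":
        return x  # plain Gaussian on the linear scale (no truncation)
    return inverse_scale_transform(x, spec.scale)


def llo_median(p, params: LLOParams):
    """Median LLO response; identity for gamma = 1, fixed point at p0."""
    lam = params.gamma * log_odds(p) + (1 - params.gamma) * log_odds(params.p0)
    return inverse_scale_transform(lam, "logodds")


def llo_sample(p, params: LLOParams, rng):
    lam = params.gamma * log_odds(p) + (1 - params.gamma) * log_odds(params.p0)
    return inverse_scale_transform(
        lam + params.sigma_lambda * rng.standard_normal(np.shape(lam)), "logodds")


def llo_params_to_model(params: LLOParams) -> dict:
    """Express LLO in the (eta, lambda0) parameterization of the registry."""
    return {"eta": params.gamma,
            "lambda0": (1 - params.gamma) * float(log_odds(params.p0)),
            "sigma_lambda": params.sigma_lambda}


def blo_median(p, N, params: BLOParams):
    return model_median(p, N, BLO_SPEC, params.as_dict())


def blo_sample(p, N, params: BLOParams, rng):
    return model_sample(p, N, BLO_SPEC, params.as_dict(), rng)


# ---------------------------------------------------------------- likelihood

def clip_responses(pi, eps: float = EPS_CLIP):
    return np.clip(np.asarray(pi, dtype=float), eps, 1.0 - eps)


def _log_jacobian(pi, scale: str):
    """log dz/dpi of the scale transform (change of variables to pi)."""
    if scale == "logodds":
        return -np.log(pi * (1.0 - pi))
    if scale == "prelec":
        return -np.log(pi) - np.log(-np.log(pi))
    return np.zeros_like(pi)


def neg_log_likelihood(responses, spec: ModelSpec, params: dict,
                       eps_clip: float = EPS_CLIP,
                       include_jacobian: bool = True) -> float:
    """Negative log likelihood of reported proportions under a model.

    ``responses`` is a table (DataFrame or dict of arrays) with columns
    ``p``, ``N`` and ``pi``.  Reports are clipped away from 0 and 1 before
    the scale transform so that boundary clicks keep finite likelihood.

    The Gaussian noise lives on the model's transformed scale; by default
    the change-of-variables Jacobian is included so the value is a density
    over the observed proportion and is comparable across models with
    different scales (without it, models on different scales cannot be
    compared by likelihood-based criteria).  ``include_jacobian=False``
    returns the density over the transformed response instead.
    """
    p = np.asarray(responses["p"], dtype=float)
    N = np.asarray(responses["N"], dtype=float)
    pi = clip_responses(np.asarray(responses["pi"], dtype=float), eps_clip)
    if p.size == 0:
        raise ValueError("empty response table")
    spec = get_model(spec)
    mean = transformed_mean(p, N, spec, params)
    z = scale_transform(pi, spec.scale)
    sigma = params["sigma_lambda"]
    resid = z - mean
    nll = 0.5 * p.size * np.log(2 * np.pi * sigma ** 2) + np.sum(resid ** 2) / (2 * sigma ** 2)
    if include_jacobian:
        nll -= np.sum(_log_jacobian(pi, spec.scale))
    return float(nll)


# ------------------------------------------------------------ kernel smoother

def kernel_smooth(x_query, x_obs, y_obs, h: float = 0.03):
    """Nadaraya-Watson kernel regression with a Gaussian kernel.

    Queries whose kernel weights all underflow to zero are returned as NaN
    (flagged with a warning) rather than silently zero.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    x_obs = np.asarray(x_obs, dtype=float)
    y_obs = np.asarray(y_obs, dtype=float)
    if x_obs.size != y_obs.size or x_obs.size < 1:
        raise ValueError("x_obs and y_obs must be equal-length and non-empty")
    xq = np.atleast_1d(np.asarray(x_query, dtype=float))
    K = np.exp(-0.5 * ((xq[:, None] - x_obs[None, :]) / h) ** 2) / np.sqrt(2 * np.pi)
    wsum = K.sum(axis=1)
    dead = wsum == 0.0
    if np.any(dead):
        warnings.warn("kernel weights underflowed to zero at some query points; "
                      "returning NaN there", RuntimeWarning)
    with np.errstate(invalid="ignore"):
        out = K @ y_obs / wsum
    out[dead] = np.nan
    return out if np.ndim(x_query) else float(out[0])
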