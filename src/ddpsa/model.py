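"""Generative model: likelihood, wind-kernel stick-breaking prior, and priors.

The observation model for the concentration ``y[p, t]`` of size bin ``p`` at
time step ``t`` is log-normal with a multiplicative, bin-specific error::

    log y[p, t] ~ Normal(log mu[p, t], sigma[p])
    mu[p, t]    = sum_k lam[p, k] * f[k, t],      f[k, t] = s[k, t] * c[t]

``lam[:, k]`` is the source profile of component ``k`` (a probability vector
over size bins), ``c[t]`` the total concentration (log-normal with mean
``mu_c`` and sd ``sigma_c``), and ``s[:, t]`` the per-time mixing weights.

The weights follow a truncated, covariate-dependent stick-breaking process:
with truncation level K the first K-1 break proportions are

    xi[k, t] = w[k, t] * eta[k, t],   eta[k, t] ~ Beta(1, alpha),

and the last break takes the remaining mass (``xi[K-1, t] = 1``).  The wind
kernel ``w`` is Gaussian in wind speed and in a sine transform of wind
direction,

    w[k, t] = exp(-(nu1[k] - ws[t])^2 / (2 h1[k]))
            * exp(-sin((nu2[k] - wd[t]) * pi / 360)^2 / (2 h2[k])),

so that each component is boosted near its preferred wind speed ``nu1[k]``
and direction ``nu2[k]``; when ``w == 1`` everywhere the construction reduces
to an ordinary time-varying Dirichlet-process stick-breaking prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import NamedTuple

import numpy as np
import yaml
from scipy import stats

from .containers import PNSDMatrix, WindSeries

__all__ = [
    "ModelConfig",
    "ParameterState",
    "LatentDerived",
    "WindSeries",
    "wind_kernel",
    "stick_break",
    "compute_latents",
    "log_likelihood",
    "log_prior",
    "beta_stick_summary",
    "BetaStickSummary",
]

# eta is kept strictly inside (0, 1) so logit reparameterizations and the
# stick-breaking products stay finite.
ETA_EPS = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters and priors.

    All Gamma priors are shape–rate.  The defaults are minimally informative:
    vague Gamma(1, 0.001) on sigma_c and on the inverse kernel bandwidths,
    Gamma(1, 1) on the squared measurement error, a Jeffreys-type symmetric
    Dirichlet(0.5) on each source profile, and Gamma(1, 1) on the
    concentration alpha (with (1, 10) and (1, 0.1) as the usual sensitivity
    alternatives).  ``nu1_upper`` defaults to the maximum observed wind speed
    so the speed knots span the empirical covariate range.
    """

    K: int = 10
    prior_mu_c: tuple = (0.0, 10.0)           # Normal(mean, sd)
    prior_sigma_c: tuple = (1.0, 0.001)       # Gamma(shape, rate) on sigma_c
    prior_sigma_p_sq: tuple = (1.0, 1.0)      # Gamma(shape, rate) on sigma_p^2
    prior_lambda: float = 0.5                 # symmetric Dirichlet concentration
    prior_alpha: tuple = (1.0, 1.0)           # Gamma(shape, rate) on alpha
    prior_inv_h: tuple = (1.0, 0.001)         # Gamma(shape, rate) on 1/h1, 1/h2
    nu1_upper: float | None = None            # Uniform(0, nu1_upper) on nu1
    source_threshold: float = 0.01

    def __post_init__(self):
        if self.K < 2:
            raise ValueError("truncation level K must be at least 2")
        if not (0 < self.source_threshold < 1):
            raise ValueError("source_threshold must lie in (0, 1)")
        for name in ("prior_sigma_c", "prior_sigma_p_sq", "prior_alpha", "prior_inv_h"):
            shape, rate = getattr(self, name)
            if shape <= 0 or rate <= 0:
                raise ValueError(f"{name} shape/rate must be positive")
        if self.prior_lambda <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.prior_mu_c[1] <= 0:
            raise ValueError("prior_mu_c sd must be positive")
        if self.nu1_upper is not None and self.nu1_upper <= 0:
            raise ValueError("nu1_upper must be positive")

    def resolve_nu1_upper(self, wind: WindSeries) -> float:
        if self.nu1_upper is not None:
            return float(self.nu1_upper)
        return float(np.nanmax(wind.ws))

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        for k, v in list(d.items()):
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class ParameterState:
    """One realization of every model unknown.

    Shapes (P bins, T time steps, truncation K, J = K - 1):
    ``lam`` (P, K); ``eta`` (J, T); ``c`` (T,); ``sigma`` (P,);
    ``nu1``, ``nu2``, ``h1``, ``h2`` (J,); scalars ``mu_c``, ``sigma_c``,
    ``alpha``.
    """

    lam: np.ndarray
    eta: np.ndarray
    c: np.ndarray
    mu_c: float
    sigma_c: float
    sigma: np.ndarray
    alpha: float
    nu1: np.ndarray
    nu2: np.ndarray
    h1: np.ndarray
    h2: np.ndarray

    @property
    def P(self) -> int:
        return self.lam.shape[0]

    @property
    def K(self) -> int:
        return self.lam.shape[1]

    @property
    def T(self) -> int:
        return len(self.c)

    def copy(self) -> "ParameterState":
        return ParameterState(
            lam=self.lam.copy(), eta=self.eta.copy(), c=self.c.copy(),
            mu_c=float(self.mu_c), sigma_c=float(self.sigma_c),
            sigma=self.sigma.copy(), alpha=float(self.alpha),
            nu1=self.nu1.copy(), nu2=self.nu2.copy(),
            h1=self.h1.copy(), h2=self.h2.copy(),
        )

    def validate(self, atol: float = 1e-10) -> "ParameterState":
        J = self.K - 1
        if self.eta.shape != (J, self.T):
            raise ValueError("eta must have shape (K-1, T)")
        for name in ("nu1", "nu2", "h1", "h2"):
            if getattr(self, name).shape != (J,):
                raise ValueError(f"{name} must have length K-1")
        if np.any(self.lam < 0):
            raise ValueError("profile entries must be nonnegative")
        colsums = self.lam.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > atol):
            raise ValueError("profile columns must sum to 1")
        if np.any((self.eta <= 0) | (self.eta >= 1)):
            raise ValueError("eta must lie strictly inside (0, 1)")
        for name in ("c", "sigma", "h1", "h2"):
            if np.any(np.asarray(getattr(self, name)) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.sigma_c <= 0 or self.alpha <= 0:
            raise ValueError("sigma_c and alpha must be positive")
        if np.any((self.nu2 < 0) | (self.nu2 >= 360)):
            raise ValueError("nu2 must lie in [0, 360)")
        return self


@dataclass
class LatentDerived:
    """Quantities derived deterministically from a state and the wind."""

    w: np.ndarray    # (J, T) kernel weights in (0, 1]
    xi: np.ndarray   # (K, T) break proportions, last row 1
    s: np.ndarray    # (K, T) mixing weights, columns sum to 1
    f: np.ndarray    # (K, T) source contributions s * c
    mu: np.ndarray   # (P, T) model mean


def wind_kernel(ws, wd, nu1, nu2, h1, h2):
    """Gaussian wind kernel, bounded by 1 with mode at (nu1, nu2).

    ``wd`` and ``nu2`` are in degrees; the direction term uses
    ``sin((nu2 - wd) * pi / 360)`` so the kernel is periodic in ``wd`` with
    period 360 and peaks whenever the direction matches the knot.
    Broadcasts over array arguments.
    """
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    if np.any(h1 <= 0) or np.any(h2 <= 0):
        raise ValueError("kernel bandwidths must be positive")
    ws = np.asarray(ws, dtype=float)
    wd = np.asarray(wd, dtype=float)
    speed_term = -((np.asarray(nu1, dtype=float) - ws) ** 2) / (2.0 * h1)
    ang = np.sin((np.asarray(nu2, dtype=float) - wd) * np.pi / 360.0)
    dir_term = -(ang ** 2) / (2.0 * h2)
    return np.exp(speed_term + dir_term)


def stick_break(xi: np.ndarray) -> np.ndarray:
    """Map break proportions to mixing weights.

    ``s[0] = xi[0]``, ``s[k] = xi[k] * prod_{l<k}(1 - xi[l])``.  The last
    break must equal 1 so the weights sum to 1 exactly.  Accepts a length-K
    vector or a (K, T) matrix (broken along axis 0).
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi < 0) or np.any(xi > 1):
        raise ValueError("break proportions must lie in [0, 1]")
    if not np.all(xi[-1] == 1.0):
        raise ValueError("the last break proportion must equal 1")
    remain = np.cumprod(1.0 - xi[:-1], axis=0)
    s = xi.copy()
    s[1:] *= remain
    return s


def compute_latents(state: ParameterState, wind: WindSeries) -> LatentDerived:
    """Evaluate w, xi, s, f and mu for a state under given wind covariates."""
    T = state.T
    if len(wind) != T:
        raise ValueError("wind series length does not match state T")
    w = wind_kernel(
        wind.ws[None, :], wind.wd[None, :],
        state.nu1[:, None], state.nu2[:, None],
        state.h1[:, None], state.h2[:, None],
    )
    xi = np.vstack([w * state.eta, np.ones((1, T))])
    s = stick_break(xi)
    f = s * state.c[None, :]
    mu = state.lam @ f
    return LatentDerived(w=w, xi=xi, s=s, f=f, mu=mu)


def log_likelihood(state: ParameterState, data: PNSDMatrix, wind: WindSeries) -> float:
    """Log-normal log likelihood over observed cells; missing cells contribute 0."""
    lat = compute_latents(state, wind)
    obs = ~data.missing_mask
    if np.any(lat.mu[obs] <= 0):
        raise ValueError("model mean must be positive at observed cells")
    y = data.values[obs]
    if np.any(y <= 0):
        raise ValueError("observed concentrations must be strictly positive")
    sig = np.broadcast_to(state.sigma[:, None], lat.mu.shape)[obs]
    z = (np.log(y) - np.log(lat.mu[obs])) / sig
    return float(np.sum(-np.log(sig) - 0.5 * np.log(2.0 * np.pi) - 0.5 * z * z))


def log_prior(state: ParameterState, config: ModelConfig, wind: WindSeries) -> float:
    """Joint log prior density of the state.

    The density is taken over the coordinates (mu_c, sigma_c, {sigma_p^2},
    {lam columns}, alpha, {eta}, {nu1}, {nu2}, {h}, {log c}): the Gamma(1, 1)
    measurement-error prior is evaluated on the variance scale as specified,
    the Gamma priors on the inverse bandwidths are evaluated in h-space (with
    the 1/h change-of-variables term), and the hierarchical Normal(mu_c,
    sigma_c) layer on log c lives here, not in the likelihood.  Out-of-support
    states return -inf.
    """
    J = state.K - 1
    nu1_upper = config.resolve_nu1_upper(wind)
    # support checks
    if (
        np.any(state.lam <= 0)
        or np.any((state.eta <= 0) | (state.eta >= 1))
        or np.any(state.c <= 0)
        or state.sigma_c <= 0
        or state.alpha <= 0
        or np.any(state.sigma <= 0)
        or np.any(state.h1 <= 0)
        or np.any(state.h2 <= 0)
        or np.any((state.nu1 < 0) | (state.nu1 > nu1_upper))
        or np.any((state.nu2 < 0) | (state.nu2 >= 360))
    ):
        return -np.inf

    lp = 0.0
    m0, s0 = config.prior_mu_c
    lp += stats.norm.logpdf(state.mu_c, loc=m0, scale=s0)
    a, b = config.prior_sigma_c
    lp += stats.gamma.logpdf(state.sigma_c, a=a, scale=1.0 / b)
    a, b = config.prior_sigma_p_sq
    lp += stats.gamma.logpdf(state.sigma ** 2, a=a, scale=1.0 / b).sum()
    conc = np.full(state.P, config.prior_lambda)
    for k in range(state.K):
        col = state.lam[:, k]
        lp += stats.dirichlet.logpdf(col / col.sum(), conc)
    a, b = config.prior_alpha
    lp += stats.gamma.logpdf(state.alpha, a=a, scale=1.0 / b)
    lp += stats.beta.logpdf(state.eta, 1.0, state.alpha).sum()
    a, b = config.prior_inv_h
    for h in (state.h1, state.h2):
        # Gamma prior on 1/h evaluated in h-space: + log|d(1/h)/dh| = -2 log h
        lp += (stats.gamma.logpdf(1.0 / h, a=a, scale=1.0 / b) - 2.0 * np.log(h)).sum()
    lp += -J * np.log(nu1_upper) - J * np.log(360.0)
    lp += stats.norm.logpdf(np.log(state.c), loc=state.mu_c, scale=state.sigma_c).sum()
    return float(lp)


class BetaStickSummary(NamedTuple):
    median: float
    prob_below: float


def beta_stick_summary(alpha: float, x: float = 0.66) -> BetaStickSummary:
    """Closed-form summaries of a single Beta(1, alpha) break proportion.

    Returns the median break-off distance ``1 - 0.5**(1/alpha)`` and the
    probability ``P(break < x) = 1 - (1 - x)**alpha``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 < x < 1):
        raise ValueError("x must lie in (0, 1)")
    median = 1.0 - 0.5 ** (1.0 / alpha)
    prob = 1.0 - (1.0 - x) ** alpha
    return BetaStickSummary(median=float(median), prob_below=float(prob))
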