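"""Posterior sampling by adaptive Metropolis-within-Gibbs.

The sampler updates blocks {profile columns, break proportions, log total
concentrations, log measurement sds, mu_c, log sigma_c, log alpha, speed
knots, circular direction knots, log bandwidths} with random-walk proposals
on transformed scales (additive-logistic for the profile simplex, logit for
eta, log for positive scalars, wrap-around for the direction knots),
targeting ``log_likelihood + log_prior``.  Coordinates that are
conditionally independent given the rest (the per-time-step quantities
eta[k, :], c, and the per-bin sigma) are proposed and accepted jointly as
vectorized one-dimensional Metropolis moves, which keeps the per-iteration
cost at a few dense P×T operations.

Proposal scales adapt toward standard acceptance targets during burn-in
only and are frozen afterwards, so the kept draws come from a fixed kernel.
Missing observations (whole time steps) are drawn each kept iteration from
the posterior predictive ``exp(Normal(log mu[p, t], sigma[p]))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import expit

from .containers import PNSDMatrix, WindSeries
from .model import (
    ETA_EPS,
    ModelConfig,
    ParameterState,
    log_likelihood,
    log_prior,
    stick_break,
    wind_kernel,
)

__all__ = [
    "MCMCSettings",
    "PosteriorDraws",
    "initialize_state",
    "run_mcmc",
    "gelman_rubin_split",
    "impute_missing",
    "save_draws",
    "load_draws",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_CHAIN_SEED_OFFSET = 100_003  # fixed per-chain seed spacing

# Robbins-Monro acceptance targets: 0.44 for univariate coordinates,
# 0.234 for the multivariate simplex columns.
_TARGET_UNI = 0.44
_TARGET_MULTI = 0.234


@dataclass
class MCMCSettings:
    """Run length, thinning and reproducibility settings.

    The defaults mirror a long production run (120k iterations, half burn-in,
    1-in-60 thinning); tests and examples pass much smaller values.
    """

    n_iter: int = 120_000
    burn_in: int = 60_000
    thin: int = 60
    seed: int = 0
    n_chains: int = 1
    proposal_scales: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_draws(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


@dataclass
class PosteriorDraws:
    """Thinned post-burn-in chains plus per-draw missing-cell imputations."""

    chains: list            # list (per chain) of lists of ParameterState
    imputed_y: list         # list (per chain) of (n_draws, n_missing) arrays
    missing_cells: np.ndarray   # (n_missing, 2) of (p, t)
    acceptance_rates: dict
    settings: MCMCSettings
    wind: WindSeries

    @property
    def draws(self) -> list:
        return [d for chain in self.chains for d in chain]

    @property
    def n_draws(self) -> int:
        return sum(len(c) for c in self.chains)

    def stack(self, name: str) -> np.ndarray:
        """Stack one parameter across all chains: shape (n_draws, *param shape)."""
        return np.array([np.asarray(getattr(d, name)) for d in self.draws])

    def imputed_stack(self) -> np.ndarray:
        if not len(self.imputed_y):
            return np.empty((0, 0))
        return np.concatenate(self.imputed_y, axis=0)


def initialize_state(data: PNSDMatrix | None, wind: WindSeries,
                     config: ModelConfig, seed: int) -> ParameterState:
    """Deterministic-given-seed starting point built from data moments.

    Totals seed c (geometric mean of observed totals at missing steps),
    perturbed normalized row means seed the profile columns, log-scale row
    sds seed sigma, wind-speed quantiles seed the speed knots and equally
    spaced angles the direction knots.
    """
    rng = np.random.default_rng(seed)
    wind.validate()
    T = len(wind)
    K = config.K
    J = K - 1

    if data is None:
        # prior-only initialization: no data moments to use
        P = 3
        c = np.exp(rng.normal(0.0, 1.0, size=T))
        lam = rng.dirichlet(np.ones(P), size=K).T
        sigma = np.ones(P)
        mu_c, sigma_c = 0.0, 1.0
    else:
        if data.n_times != T:
            raise ValueError("data and wind lengths differ")
        data.require_positive()
        P = data.n_bins
        obs_cols = ~data.missing_cols
        if not obs_cols.any():
            raise ValueError("all time steps are missing; nothing to initialize from")
        totals = data.values.sum(axis=0)
        gm = float(np.exp(np.mean(np.log(totals[obs_cols]))))
        c = np.where(obs_cols, totals, gm)
        c = np.maximum(c, 1e-12)
        rowmean = data.values[:, obs_cols].mean(axis=1)
        rowmean = np.maximum(rowmean, 1e-12)
        base = rowmean / rowmean.sum()
        lam = np.empty((P, K))
        for k in range(K):
            col = base * np.exp(0.4 * rng.standard_normal(P))
            lam[:, k] = col / col.sum()
        logy = np.log(data.values[:, obs_cols])
        sigma = np.maximum(logy.std(axis=1), 0.05)
        mu_c = float(np.mean(np.log(c)))
        sigma_c = max(float(np.std(np.log(c))), 0.1)

    eta = np.clip(rng.beta(1.0, 1.0, size=(J, T)), ETA_EPS, 1 - ETA_EPS)
    qs = (np.arange(J) + 1.0) / (J + 1.0)
    nu1 = np.quantile(wind.ws, qs)
    nu1 = np.minimum(nu1, config.resolve_nu1_upper(wind))
    nu2 = np.linspace(0.0, 360.0, J, endpoint=False)
    h1 = np.full(J, max(float(np.var(wind.ws)), 0.1))
    h2 = np.full(J, max(float(np.var(np.sin(wind.wd * np.pi / 360.0) ** 2)), 0.05))
    return ParameterState(
        lam=lam, eta=eta, c=c, mu_c=mu_c, sigma_c=sigma_c, sigma=sigma,
        alpha=1.0, nu1=nu1, nu2=nu2, h1=h1, h2=h2,
    ).validate()


class _Sampler:
    """One-chain adaptive Metropolis-within-Gibbs kernel with cached latents."""

    def __init__(self, data, wind, config, settings, seed):
        self.rng = np.random.default_rng(seed)
        self.wind = wind
        self.config = config
        self.state = initialize_state(data, wind, config, seed)
        st = self.state
        self.P, self.K, self.T = st.P, st.K, st.T
        self.J = self.K - 1
        self.nu1_upper = config.resolve_nu1_upper(wind)

        if data is None:
            self.obs = np.zeros((self.P, self.T), dtype=bool)
            self.logy = np.zeros((self.P, self.T))
            self.missing_cells = np.empty((0, 2), dtype=int)
        else:
            self.obs = ~data.missing_mask
            self.logy = np.where(data.missing_mask, 0.0, np.log(
                np.where(data.missing_mask, 1.0, data.values)))
            self.missing_cells = np.argwhere(data.missing_mask)
        self.prior_only = not self.obs.any()

        # latent caches
        self.w = wind_kernel(wind.ws[None, :], wind.wd[None, :],
                             st.nu1[:, None], st.nu2[:, None],
                             st.h1[:, None], st.h2[:, None])
        self.xi = np.vstack([self.w * st.eta, np.ones((1, self.T))])
        self.s = stick_break(self.xi)
        self.f = self.s * st.c[None, :]
        self.mu = st.lam @ self.f
        self.cll = self._cell_ll(self.mu, st.sigma)
        self.col_ll = self.cll.sum(axis=0)

        sc = dict(settings.proposal_scales)
        self.scales = {
            "lam": np.full(self.K, sc.get("lam", 0.10)),
            "eta": np.full((self.J, self.T), sc.get("eta", 1.0)),
            "c": np.full(self.T, sc.get("c", 0.2)),
            "sigma": np.full(self.P, sc.get("sigma", 0.3)),
            "mu_c": np.array(sc.get("mu_c", 0.5)),
            "sigma_c": np.array(sc.get("sigma_c", 0.5)),
            "alpha": np.array(sc.get("alpha", 0.5)),
            "nu1": np.full(self.J, sc.get("nu1", 0.5)),
            "nu2": np.full(self.J, sc.get("nu2", 30.0)),
            "h1": np.full(self.J, sc.get("h1", 0.5)),
            "h2": np.full(self.J, sc.get("h2", 0.5)),
        }
        self.acc_sum = {k: 0.0 for k in self.scales}
        self.acc_n = {k: 0 for k in self.scales}
        self.adapting = True
        self._step = 0

    # -- likelihood helpers -------------------------------------------------

    def _cell_ll(self, mu, sigma):
        if self.prior_only:
            return np.zeros_like(mu)
        # unobserved cells are zeroed via `where`, so extreme proposals that
        # overflow mu at missing columns cannot poison the accept ratios
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            z = (self.logy - np.log(mu)) / sigma[:, None]
            out = -np.log(sigma)[:, None] - 0.5 * _LOG2PI - 0.5 * z * z
        return np.where(self.obs, out, 0.0)

    # -- adaptation ---------------------------------------------------------

    def _adapt(self, name, acc_indicator, target):
        if self.adapting:
            gam = min(0.5, (self._step + 1) ** -0.6)
            self.scales[name] *= np.exp(gam * (np.asarray(acc_indicator, float) - target))
            np.clip(self.scales[name], 1e-6, 1e4, out=self.scales[name])
        else:
            self.acc_sum[name] += float(np.mean(acc_indicator))
            self.acc_n[name] += 1

    # -- block updates ------------------------------------------------------

    def update_lam(self):
        st, rng = self.state, self.rng
        a = self.config.prior_lambda
        accs = np.zeros(self.K)
        for k in range(self.K):
            col = st.lam[:, k]
            z = np.log(col[:-1]) - np.log(col[-1])
            zp = z + self.scales["lam"][k] * rng.standard_normal(self.P - 1)
            zfull = np.append(zp, 0.0)
            zfull -= zfull.max()
            colp = np.exp(zfull)
            colp /= colp.sum()
            colp = np.clip(colp, 1e-300, None)
            mu_p = self.mu + np.outer(colp - col, self.f[k])
            cll_p = self._cell_ll(mu_p, st.sigma)
            logr = (cll_p.sum() - self.cll.sum()
                    + a * (np.log(colp).sum() - np.log(col).sum()))
            if np.log(rng.random()) < logr:
                st.lam[:, k] = colp
                self.mu = mu_p
                self.cll = cll_p
                self.col_ll = cll_p.sum(axis=0)
                accs[k] = 1.0
        self._adapt("lam", accs, _TARGET_MULTI)

    def update_eta(self):
        st, rng = self.state, self.rng
        acc_mat = np.zeros((self.J, self.T))
        for k in range(self.J):
            ek = st.eta[k]
            z = np.log(ek) - np.log1p(-ek)
            zp = z + self.scales["eta"][k] * rng.standard_normal(self.T)
            ep = np.clip(expit(zp), ETA_EPS, 1 - ETA_EPS)
            xi_p = self.xi.copy()
            xi_p[k] = self.w[k] * ep
            s_p = stick_break(xi_p)
            mu_p = st.lam @ (s_p * st.c[None, :])
            cll_p = self._cell_ll(mu_p, st.sigma)
            col_p = cll_p.sum(axis=0)
            dpr = ((st.alpha - 1.0) * (np.log1p(-ep) - np.log1p(-ek))
                   + np.log(ep) + np.log1p(-ep) - np.log(ek) - np.log1p(-ek))
            acc = np.log(rng.random(self.T)) < (col_p - self.col_ll + dpr)
            if acc.any():
                st.eta[k, acc] = ep[acc]
                self.xi[k, acc] = xi_p[k, acc]
                self.s[:, acc] = s_p[:, acc]
                self.f[:, acc] = self.s[:, acc] * st.c[acc]
                self.mu[:, acc] = mu_p[:, acc]
                self.cll[:, acc] = cll_p[:, acc]
                self.col_ll[acc] = col_p[acc]
            acc_mat[k] = acc
            self._adapt_row("eta", k, acc)
        if not self.adapting:
            self.acc_sum["eta"] += float(acc_mat.mean())
            self.acc_n["eta"] += 1

    def _adapt_row(self, name, k, acc_indicator):
        if self.adapting:
            gam = min(0.5, (self._step + 1) ** -0.6)
            val = self.scales[name][k] * np.exp(
                gam * (np.asarray(acc_indicator, float) - _TARGET_UNI))
            self.scales[name][k] = np.clip(val, 1e-6, 1e4)

    def update_c(self):
        st, rng = self.state, self.rng
        lc = np.log(st.c)
        lcp = lc + self.scales["c"] * rng.standard_normal(self.T)
        # keep exp() finite; only reachable in prior-only runs where the
        # vague sigma_c prior lets log c wander by hundreds
        np.clip(lcp, -700.0, 700.0, out=lcp)
        with np.errstate(over="ignore", invalid="ignore"):
            ratio = np.exp(lcp - lc)
            mu_p = self.mu * ratio[None, :]
            cll_p = self._cell_ll(mu_p, st.sigma)
            col_p = cll_p.sum(axis=0)
            dpr = (-0.5 * ((lcp - st.mu_c) / st.sigma_c) ** 2
                   + 0.5 * ((lc - st.mu_c) / st.sigma_c) ** 2)
            acc = np.log(rng.random(self.T)) < (col_p - self.col_ll + dpr)
            if acc.any():
                st.c[acc] = np.exp(lcp[acc])
                self.f[:, acc] *= ratio[acc]
                self.mu[:, acc] = mu_p[:, acc]
                self.cll[:, acc] = cll_p[:, acc]
                self.col_ll[acc] = col_p[acc]
        self._adapt("c", acc, _TARGET_UNI)

    def update_sigma(self):
        st, rng = self.state, self.rng
        x = np.log(st.sigma)
        xp = x + self.scales["sigma"] * rng.standard_normal(self.P)
        sp = np.exp(xp)
        cll_p = self._cell_ll(self.mu, sp)
        a0, b0 = self.config.prior_sigma_p_sq
        dpr = 2.0 * a0 * (xp - x) - b0 * (np.exp(2 * xp) - np.exp(2 * x))
        logr = cll_p.sum(axis=1) - self.cll.sum(axis=1) + dpr
        acc = np.log(rng.random(self.P)) < logr
        if acc.any():
            st.sigma[acc] = sp[acc]
            self.cll[acc] = cll_p[acc]
            self.col_ll = self.cll.sum(axis=0)
        self._adapt("sigma", acc, _TARGET_UNI)

    def update_mu_c(self):
        st, rng = self.state, self.rng
        prop = st.mu_c + float(self.scales["mu_c"]) * rng.standard_normal()
        m0, s0 = self.config.prior_mu_c
        lc = np.log(st.c)
        logr = (-0.5 * ((prop - m0) / s0) ** 2 + 0.5 * ((st.mu_c - m0) / s0) ** 2
                - 0.5 * np.sum(((lc - prop) / st.sigma_c) ** 2)
                + 0.5 * np.sum(((lc - st.mu_c) / st.sigma_c) ** 2))
        acc = np.log(rng.random()) < logr
        if acc:
            st.mu_c = prop
        self._adapt("mu_c", acc, _TARGET_UNI)

    def update_sigma_c(self):
        st, rng = self.state, self.rng
        x = np.log(st.sigma_c)
        xp = x + float(self.scales["sigma_c"]) * rng.standard_normal()
        scp = np.exp(xp)
        a, b = self.config.prior_sigma_c
        ss = np.sum((np.log(st.c) - st.mu_c) ** 2)
        logr = (a * (xp - x) - b * (scp - st.sigma_c)
                - self.T * (xp - x)
                - 0.5 * ss * (scp ** -2 - st.sigma_c ** -2))
        acc = np.log(rng.random()) < logr
        if acc:
            st.sigma_c = scp
        self._adapt("sigma_c", acc, _TARGET_UNI)

    def update_alpha(self):
        st, rng = self.state, self.rng
        x = np.log(st.alpha)
        xp = x + float(self.scales["alpha"]) * rng.standard_normal()
        ap = np.exp(xp)
        a, b = self.config.prior_alpha
        S = np.sum(np.log1p(-st.eta))
        n_eta = st.eta.size
        logr = (a * (xp - x) - b * (ap - st.alpha)
                + n_eta * (xp - x) + (ap - st.alpha) * S)
        acc = np.log(rng.random()) < logr
        if acc:
            st.alpha = ap
        self._adapt("alpha", acc, _TARGET_UNI)

    def _try_kernel(self, k, nu1p, nu2p, h1p, h2p, dpr):
        """Attempt replacing source k's kernel parameters; return accept flag."""
        st = self.state
        wk = wind_kernel(self.wind.ws, self.wind.wd, nu1p, nu2p, h1p, h2p)
        xi_p = self.xi.copy()
        xi_p[k] = wk * st.eta[k]
        s_p = stick_break(xi_p)
        mu_p = st.lam @ (s_p * st.c[None, :])
        cll_p = self._cell_ll(mu_p, st.sigma)
        logr = cll_p.sum() - self.cll.sum() + dpr
        if np.log(self.rng.random()) < logr:
            st.nu1[k], st.nu2[k], st.h1[k], st.h2[k] = nu1p, nu2p, h1p, h2p
            self.w[k] = wk
            self.xi = xi_p
            self.s = s_p
            self.f = s_p * st.c[None, :]
            self.mu = mu_p
            self.cll = cll_p
            self.col_ll = cll_p.sum(axis=0)
            return True
        return False

    def update_kernels(self):
        st, rng = self.state, self.rng
        ah, bh = self.config.prior_inv_h
        for k in range(self.J):
            # speed knot, Uniform(0, nu1_upper) prior
            prop = st.nu1[k] + self.scales["nu1"][k] * rng.standard_normal()
            acc = False
            if 0.0 <= prop <= self.nu1_upper:
                acc = self._try_kernel(k, prop, st.nu2[k], st.h1[k], st.h2[k], 0.0)
            self._adapt_row("nu1", k, acc)
            self._count(k, "nu1", acc)

            # direction knot, circular random walk on [0, 360)
            prop = (st.nu2[k] + self.scales["nu2"][k] * rng.standard_normal()) % 360.0
            acc = self._try_kernel(k, st.nu1[k], prop, st.h1[k], st.h2[k], 0.0)
            self._adapt_row("nu2", k, acc)
            self._count(k, "nu2", acc)

            # bandwidths: log random walk, Gamma prior on 1/h
            for name, cur in (("h1", st.h1[k]), ("h2", st.h2[k])):
                x = np.log(cur)
                xp = x + self.scales[name][k] * rng.standard_normal()
                hp = np.exp(xp)
                dpr = -ah * (xp - x) - bh * (np.exp(-xp) - np.exp(-x))
                if name == "h1":
                    acc = self._try_kernel(k, st.nu1[k], st.nu2[k], hp, st.h2[k], dpr)
                else:
                    acc = self._try_kernel(k, st.nu1[k], st.nu2[k], st.h1[k], hp, dpr)
                self._adapt_row(name, k, acc)
                self._count(k, name, acc)

    def _count(self, k, name, acc):
        if not self.adapting:
            self.acc_sum[name] += float(acc) / self.J
            self.acc_n[name] += 1 if k == self.J - 1 else 0

    def sweep(self):
        self.update_lam()
        self.update_eta()
        self.update_c()
        self.update_sigma()
        self.update_mu_c()
        self.update_sigma_c()
        self.update_alpha()
        self.update_kernels()
        self._step += 1

    def impute(self) -> np.ndarray:
        if len(self.missing_cells) == 0:
            return np.empty(0)
        p, t = self.missing_cells[:, 0], self.missing_cells[:, 1]
        draw = (np.log(self.mu[p, t])
                + self.state.sigma[p] * self.rng.standard_normal(len(p)))
        return np.exp(draw)

    def acceptance_rates(self) -> dict:
        """Post-burn-in acceptance per block (mean over coordinates)."""
        return {name: (self.acc_sum[name] / n if (n := self.acc_n[name]) else np.nan)
                for name in self.acc_sum}


def run_mcmc(data: PNSDMatrix | None, wind: WindSeries, config: ModelConfig,
             settings: MCMCSettings) -> PosteriorDraws:
    """Sample the posterior (or the prior, when ``data`` is None).

    Runs ``settings.n_chains`` independent chains with per-chain seeds at
    fixed offsets from ``settings.seed``; proposal-scale adaptation happens
    during burn-in only.  Fully reproducible given the seed.
    """
    chains = []
    imputed = []
    acc_all = []
    missing_cells = np.empty((0, 2), dtype=int)
    for ci in range(settings.n_chains):
        seed = settings.seed + _CHAIN_SEED_OFFSET * ci
        smp = _Sampler(data, wind, config, settings, seed)
        missing_cells = smp.missing_cells

        ll0 = float(smp.cll.sum())
        lp0 = log_prior(smp.state, config, wind)
        if not np.isfinite(ll0):
            raise RuntimeError("non-finite log-likelihood at initialization")
        if not np.isfinite(lp0):
            raise RuntimeError("non-finite log-prior at initialization")

        kept: list[ParameterState] = []
        imps: list[np.ndarray] = []
        for i in range(settings.n_iter):
            if i == settings.burn_in:
                smp.adapting = False
            smp.sweep()
            if i >= settings.burn_in and (i - settings.burn_in) % settings.thin == settings.thin - 1:
                kept.append(smp.state.copy().validate())
                imps.append(smp.impute())
        chains.append(kept)
        imputed.append(np.array(imps) if imps and imps[0].size else
                       np.empty((len(imps), 0)))
        acc_all.append(smp.acceptance_rates())

    acc = {k: float(np.mean([a[k] for a in acc_all])) for k in acc_all[0]}
    return PosteriorDraws(chains=chains, imputed_y=imputed,
                          missing_cells=missing_cells,
                          acceptance_rates=acc, settings=settings, wind=wind)


def gelman_rubin_split(chain) -> float:
    """Split-half potential scale reduction factor for one scalar chain.

    The chain is split into two halves of n = len // 2 draws (the middle
    element is dropped for odd lengths); with W the mean within-half
    variance and B the between-half variance,
    ``R-hat = sqrt(((n - 1)/n * W + B/n) / W)``.
    """
    x = np.asarray(chain, dtype=float)
    if x.ndim != 1 or len(x) < 4:
        raise ValueError("need a 1-D chain of length >= 4")
    n = len(x) // 2
    a, b = x[:n], x[len(x) - n:]
    W = 0.5 * (a.var(ddof=1) + b.var(ddof=1))
    if W == 0:
        raise ValueError("zero within-half variance (constant chain)")
    means = np.array([a.mean(), b.mean()])
    B = n * means.var(ddof=1)
    return float(np.sqrt(((n - 1) / n * W + B / n) / W))


def impute_missing(draws: PosteriorDraws, data: PNSDMatrix):
    """Posterior-predictive mean and 95% interval per missing cell.

    Returns a DataFrame with one row per missing (p, t) cell, empty when the
    panel is complete.
    """
    import pandas as pd

    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    cells = draws.missing_cells
    cols = ["p", "t", "bin_nm", "time", "mean", "lo95", "hi95"]
    if len(cells) == 0:
        return pd.DataFrame(columns=cols)
    samples = draws.imputed_stack()   # (n_draws, n_missing)
    mean = samples.mean(axis=0)
    lo, hi = np.quantile(samples, [0.025, 0.975], axis=0)
    return pd.DataFrame({
        "p": cells[:, 0],
        "t": cells[:, 1],
        "bin_nm": data.bin_labels[cells[:, 0]],
        "time": data.times[cells[:, 1]],
        "mean": mean,
        "lo95": lo,
        "hi95": hi,
    })


# -- persistence ------------------------------------------------------------

_STATE_FIELDS = ("lam", "eta", "c", "mu_c", "sigma_c", "sigma", "alpha",
                 "nu1", "nu2", "h1", "h2")


def save_draws(draws: PosteriorDraws, directory) -> None:
    """Persist draws as flat per-parameter arrays plus a JSON manifest.

    Plain ``.npy`` files are byte-deterministic, so identical runs produce
    identical draw directories.
    """
    import os

    os.makedirs(directory, exist_ok=True)
    for ci, chain in enumerate(draws.chains):
        cdir = os.path.join(directory, f"chain{ci}")
        os.makedirs(cdir, exist_ok=True)
        for name in _STATE_FIELDS:
            arr = np.array([np.asarray(getattr(d, name)) for d in chain])
            np.save(os.path.join(cdir, f"{name}.npy"), arr)
        np.save(os.path.join(cdir, "imputed_y.npy"), draws.imputed_y[ci])
    manifest = {
        "n_chains": len(draws.chains),
        "settings": asdict(draws.settings),
        "acceptance_rates": draws.acceptance_rates,
        "missing_cells": draws.missing_cells.tolist(),
        "wind_ws": draws.wind.ws.tolist(),
        "wind_wd": draws.wind.wd.tolist(),
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh)


def load_draws(directory) -> PosteriorDraws:
    import os

    path = os.path.join(directory, "manifest.json")
    try:
        with open(path) as fh:
            manifest = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt or missing draws manifest: {path}") from exc
    chains = []
    imputed = []
    for ci in range(manifest["n_chains"]):
        cdir = os.path.join(directory, f"chain{ci}")
        arrays = {}
        for name in _STATE_FIELDS + ("imputed_y",):
            fname = os.path.join(cdir, f"{name}.npy")
            try:
                arrays[name] = np.load(fname)
            except Exception as exc:
                raise ValueError(f"corrupt or missing draws file: {fname}") from exc
        n = arrays["c"].shape[0]
        chain = []
        for i in range(n):
            chain.append(ParameterState(
                lam=arrays["lam"][i], eta=arrays["eta"][i], c=arrays["c"][i],
                mu_c=float(arrays["mu_c"][i]), sigma_c=float(arrays["sigma_c"][i]),
                sigma=arrays["sigma"][i], alpha=float(arrays["alpha"][i]),
                nu1=arrays["nu1"][i], nu2=arrays["nu2"][i],
                h1=arrays["h1"][i], h2=arrays["h2"][i]))
        chains.append(chain)
        imputed.append(arrays["imputed_y"])
    settings = MCMCSettings(**manifest["settings"])
    wind = WindSeries(ws=np.array(manifest["wind_ws"]),
                      wd=np.array(manifest["wind_wd"]))
    return PosteriorDraws(
        chains=chains, imputed_y=imputed,
        missing_cells=np.array(manifest["missing_cells"], dtype=int).reshape(-1, 2),
        acceptance_rates=manifest["acceptance_rates"], settings=settings, wind=wind)
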