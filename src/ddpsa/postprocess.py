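"""Source characterization from posterior draws.

Turns :class:`~ddpsa.inference.PosteriorDraws` into the usual source-
apportionment outputs: contribution shares and the non-empty-source count,
label alignment between runs, posterior profiles (natural and logit scale),
wind-kernel surfaces, temporal summaries and correlation panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .containers import PNSDMatrix
from .inference import PosteriorDraws
from .model import compute_latents, wind_kernel

__all__ = [
    "SourceSummary",
    "source_shares",
    "count_nonempty",
    "align_labels",
    "match_profiles",
    "temporal_summary",
    "pollutant_correlations",
    "intersource_correlations",
    "kernel_surface",
    "posterior_mean_f",
    "posterior_mean_profiles",
    "summarize_sources",
]

_LOGIT_CLIP = 1e-12


@dataclass
class SourceSummary:
    """Derived quantities for one source."""

    k: int
    share: float
    profile_mean: np.ndarray
    profile_lo: np.ndarray
    profile_hi: np.ndarray
    profile_logit: np.ndarray
    kernel_grid: np.ndarray | None
    temporal_means: dict
    pollutant_corr: pd.Series | None


def _latents_per_draw(draws: PosteriorDraws):
    for d in draws.draws:
        yield compute_latents(d, draws.wind)


def posterior_mean_f(draws: PosteriorDraws) -> np.ndarray:
    """Posterior mean of the contribution matrix f (K × T)."""
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    acc = None
    for lat in _latents_per_draw(draws):
        acc = lat.f if acc is None else acc + lat.f
    return acc / draws.n_draws


def posterior_mean_profiles(draws: PosteriorDraws) -> np.ndarray:
    return draws.stack("lam").mean(axis=0)


def source_shares(draws: PosteriorDraws) -> np.ndarray:
    """Posterior-mean contribution share of each source.

    Computed per draw as ``sum_t f[k, t] / sum_t c[t]`` and then averaged,
    so the shares sum to 1 exactly for every draw and hence in the mean.
    """
    if draws.n_draws == 0:
        raise ValueError("no posterior draws")
    shares = np.zeros(draws.draws[0].K)
    for d, lat in zip(draws.draws, _latents_per_draw(draws)):
        shares += lat.f.sum(axis=1) / d.c.sum()
    return shares / draws.n_draws


def count_nonempty(shares: np.ndarray, threshold: float) -> int:
    """Number of sources whose share exceeds the threshold (e.g. 1%)."""
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    return int(np.sum(np.asarray(shares) > threshold))


def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    An = A / np.linalg.norm(A, axis=0, keepdims=True)
    Bn = B / np.linalg.norm(B, axis=0, keepdims=True)
    return An.T @ Bn


def match_profiles(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal assignment of B's columns to A's by total cosine similarity.

    Returns ``(perm, sims)`` where column ``perm[i]`` of B is matched to
    column ``i`` of A and ``sims[i]`` is the matched cosine similarity.
    Handles rectangular cases (fewer columns in A than B).
    """
    S = _cosine_matrix(A, B)
    rows, cols = linear_sum_assignment(-S)
    perm = np.empty(len(rows), dtype=int)
    sims = np.empty(len(rows))
    perm[rows] = cols
    sims[rows] = S[rows, cols]
    return perm, sims


def align_labels(draws_a: PosteriorDraws, draws_b: PosteriorDraws
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Label permutation matching run b's sources to run a's.

    Uses the optimal assignment maximizing total cosine similarity between
    the runs' posterior-mean profile columns.
    """
    A = posterior_mean_profiles(draws_a)
    B = posterior_mean_profiles(draws_b)
    if A.shape != B.shape:
        raise ValueError("runs have different P or K")
    return match_profiles(A, B)


def _grouped(series: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    df = pd.DataFrame({"g": labels, "x": series})
    out = df.groupby("g")["x"].agg(
        mean="mean", q25=lambda v: v.quantile(0.25), median="median",
        q75=lambda v: v.quantile(0.75), n="size")
    return out


def temporal_summary(draws: PosteriorDraws, data: PNSDMatrix) -> dict:
    """Posterior-mean total and per-source series grouped in time.

    Returns ``{"block": ..., "weekday": ..., "month": ...}``; each entry is
    a DataFrame of boxplot statistics (mean, quartiles, count) for the total
    concentration (column level "total") and each source.
    """
    f = posterior_mean_f(draws)
    c = draws.stack("c").mean(axis=0)
    groups = {
        "block": data.block_labels,
        "weekday": data.weekday,
        "month": data.month,
    }
    out = {}
    for name, labels in groups.items():
        tables = {"total": _grouped(c, labels)}
        for k in range(f.shape[0]):
            tables[f"source{k + 1}"] = _grouped(f[k], labels)
        out[name] = pd.concat(tables, axis=1)
    return out


def pollutant_correlations(draws: PosteriorDraws, pollutants: pd.DataFrame
                           ) -> pd.DataFrame:
    """Pearson correlation of posterior-mean f[k, :] with each pollutant.

    Pollutant missingness is handled pairwise-complete.  Rows are sources,
    columns pollutants.
    """
    f = posterior_mean_f(draws)
    if len(pollutants) != f.shape[1]:
        raise ValueError("pollutant series length does not match model time steps")
    K = f.shape[0]
    out = pd.DataFrame(index=[f"source{k + 1}" for k in range(K)],
                       columns=pollutants.columns, dtype=float)
    for col in pollutants.columns:
        x = pollutants[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if not ok.any():
            raise ValueError(f"pollutant {col!r} is entirely missing")
        for k in range(K):
            out.loc[f"source{k + 1}", col] = float(np.corrcoef(f[k, ok], x[ok])[0, 1])
    return out


def intersource_correlations(draws: PosteriorDraws) -> np.ndarray:
    """K×K Pearson correlation matrix of the posterior-mean contributions."""
    f = posterior_mean_f(draws)
    if f.shape[0] == 1:
        return np.ones((1, 1))
    C = np.corrcoef(f)
    C = 0.5 * (C + C.T)
    np.fill_diagonal(C, 1.0)
    return C


def kernel_surface(draws: PosteriorDraws, k: int, ws_grid: np.ndarray,
                   wd_grid: np.ndarray) -> np.ndarray:
    """Posterior-mean wind kernel of source k over a (ws, wd) grid.

    The last source (index K-1) takes the remaining stick-breaking mass and
    has no kernel; asking for it is an error.
    """
    K = draws.draws[0].K
    if not (0 <= k < K - 1):
        raise ValueError(
            f"source index {k} has no wind kernel: only the first K-1 = {K - 1} "
            "sources carry kernels; the last source is the truncation remainder")
    WS, WD = np.meshgrid(np.asarray(ws_grid, float), np.asarray(wd_grid, float),
                         indexing="ij")
    acc = np.zeros_like(WS)
    for d in draws.draws:
        acc += wind_kernel(WS, WD, d.nu1[k], d.nu2[k], d.h1[k], d.h2[k])
    return acc / draws.n_draws


def summarize_sources(draws: PosteriorDraws, data: PNSDMatrix,
                      pollutants: pd.DataFrame | None = None,
                      ws_grid: np.ndarray | None = None,
                      wd_grid: np.ndarray | None = None) -> list[SourceSummary]:
    """Full per-source characterization (share, profile, kernel, temporal)."""
    shares = source_shares(draws)
    lam = draws.stack("lam")                       # (n, P, K)
    prof_mean = lam.mean(axis=0)
    prof_lo, prof_hi = np.quantile(lam, [0.025, 0.975], axis=0)
    temporal = temporal_summary(draws, data)
    pcorr = pollutant_correlations(draws, pollutants) if pollutants is not None else None
    if ws_grid is None:
        ws_grid = np.linspace(0.0, float(draws.wind.ws.max()), 25)
    if wd_grid is None:
        wd_grid = np.linspace(0.0, 360.0, 37)
    K = prof_mean.shape[1]
    out = []
    for k in range(K):
        pm = prof_mean[:, k]
        clipped = np.clip(pm, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
        summary = SourceSummary(
            k=k,
            share=float(shares[k]),
            profile_mean=pm,
            profile_lo=prof_lo[:, k],
            profile_hi=prof_hi[:, k],
            profile_logit=np.log(clipped / (1 - clipped)),
            kernel_grid=(kernel_surface(draws, k, ws_grid, wd_grid)
                         if k < K - 1 else None),
            temporal_means={name: tab[f"source{k + 1}"]["mean"]
                            for name, tab in temporal.items()},
            pollutant_corr=(pcorr.loc[f"source{k + 1}"] if pcorr is not None else None),
        )
        out.append(summary)
    return out
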