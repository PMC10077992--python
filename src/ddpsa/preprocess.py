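"""Data reduction and cleaning for hourly PNSD panels.

The raw panel is high dimensional (here typically ~100 size bins × thousands
of hours) and strongly correlated across neighbouring bins and hours.  Two
greedy, correlation-driven aggregations make it tractable:

* **bin aggregation** — walk the size bins left to right; a group growing
  from bin ``p`` absorbs bin ``p+q`` while the Pearson correlation between
  the *first* bin of the group and bin ``p+q`` (over jointly observed times)
  stays at or above a threshold ``tau``; member concentrations are summed,
* **hour aggregation** — the same greedy rule over the 24 hours of day,
  correlating day-indexed series of hour ``a`` vs hour ``a+h``; one shared
  partition is used for all bins (by default a merge requires the minimum
  correlation over bins to reach ``tau``); member hours are averaged.

Cleaning then replaces exact zeros (below-detection artifacts) by half the
minimum non-zero value of the corresponding bin, and missing wind covariates
are mean-imputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AggregationPlan, PNSDMatrix, RawPNSD, WindSeries

__all__ = [
    "plan_bin_aggregation",
    "apply_bin_aggregation",
    "plan_hour_aggregation",
    "apply_hour_aggregation",
    "replace_zeros",
    "impute_covariates_mean",
    "reduction_summary",
]


def _wrap360(x):
    """Modulo 360 that never returns 360.0 (fp edge of tiny negatives)."""
    out = np.mod(x, 360.0)
    return np.where(out >= 360.0, 0.0, out) if np.ndim(out) else (
        0.0 if out >= 360.0 else float(out))


def _pairwise_corr(x: np.ndarray, y: np.ndarray, ok: np.ndarray,
                   names: tuple = ("a", "b")) -> float:
    """Pearson correlation over jointly observed entries."""
    if ok.sum() < 2:
        raise ValueError(
            f"bins {names[0]} and {names[1]} share fewer than 2 observed time points"
        )
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        # a constant series is treated as uncorrelated with anything
        return 0.0
    return float(np.corrcoef(xv, yv)[0, 1])


def plan_bin_aggregation(raw: RawPNSD, tau: float) -> AggregationPlan:
    """Greedy left-to-right partition of size bins.

    A group anchored at bin ``p`` is extended to ``p+q`` while
    ``corr(y[p], y[p+q]) >= tau``; the first bin failing the test starts a
    new group.  Correlations are Pearson on raw concentrations over jointly
    non-missing times.
    """
    if raw.n_bins < 2:
        raise ValueError("need at least 2 bins to plan an aggregation")
    obs = ~raw.missing_mask
    groups: list[list[int]] = []
    corrs: list[list[float]] = []
    p = 0
    while p < raw.n_bins:
        group = [p]
        gcorr: list[float] = []
        q = p + 1
        while q < raw.n_bins:
            ok = obs[p] & obs[q]
            r = _pairwise_corr(raw.values[p], raw.values[q], ok,
                               (raw.bin_labels[p], raw.bin_labels[q]))
            if r >= tau:
                group.append(q)
                gcorr.append(r)
                q += 1
            else:
                break
        groups.append(group)
        corrs.append(gcorr)
        p = group[-1] + 1
    return AggregationPlan(tau=tau, bin_groups=groups, bin_correlations=corrs)


def apply_bin_aggregation(raw: RawPNSD, plan: AggregationPlan) -> RawPNSD:
    """Sum concentrations within each planned bin group.

    The representative size of an aggregated bin is the geometric mean of
    its member midpoints (sizes are log-spaced); the nm endpoints of each
    group are retained in ``bin_ranges``.
    """
    if plan.bin_groups is None:
        raise ValueError("plan has no bin groups")
    flat = sorted(i for g in plan.bin_groups for i in g)
    if flat != list(range(raw.n_bins)):
        raise ValueError("plan does not cover the raw panel's bins")
    P_new = len(plan.bin_groups)
    values = np.empty((P_new, raw.n_times))
    mask = np.zeros((P_new, raw.n_times), dtype=bool)
    labels = np.empty(P_new)
    ranges = []
    for i, g in enumerate(plan.bin_groups):
        idx = list(g)
        values[i] = raw.values[idx].sum(axis=0)
        mask[i] = raw.missing_mask[idx].any(axis=0)
        member = raw.bin_labels[idx]
        labels[i] = float(np.exp(np.mean(np.log(member))))
        ranges.append((float(member[0]), float(member[-1])))
    values[mask] = np.nan
    return RawPNSD(times=raw.times, bin_labels=labels, values=np.where(mask, 0, values),
                   missing_mask=mask, bin_ranges=ranges)


def _day_hour_table(raw: RawPNSD) -> tuple[np.ndarray, np.ndarray, pd.DatetimeIndex]:
    """Reshape (P, T_hourly) into (P, n_days, 24) with an observation mask."""
    dates = raw.times.normalize()
    days = pd.DatetimeIndex(dates.unique().sort_values())
    day_pos = pd.Series(np.arange(len(days)), index=days)
    di = day_pos.loc[dates].to_numpy()
    hi = raw.times.hour.to_numpy()
    cube = np.full((raw.n_bins, len(days), 24), np.nan)
    cube[:, di, hi] = np.where(raw.missing_mask, np.nan, raw.values)
    obs = ~np.isnan(cube)
    return cube, obs, days


def plan_hour_aggregation(raw: RawPNSD, tau: float, method: str = "min") -> AggregationPlan:
    """Greedy partition of the 24 hours of day shared by all bins.

    For each bin, hour ``a`` and candidate hour ``a+h``, the correlation of
    the two across-days series is computed (anchored to the first hour of the
    growing group).  With ``method='min'`` (default) a merge requires the
    minimum correlation over bins to reach ``tau``; with ``method='pooled'``
    all bins' day-pairs are pooled into a single correlation.
    """
    if method not in ("min", "pooled"):
        raise ValueError("method must be 'min' or 'pooled'")
    cube, obs, days = _day_hour_table(raw)
    if len(days) < 2:
        raise ValueError("need at least 2 days of data to aggregate hours")

    def merge_corr(a: int, b: int) -> float:
        if method == "pooled":
            ok = (obs[:, :, a] & obs[:, :, b]).ravel()
            return _pairwise_corr(cube[:, :, a].ravel(), cube[:, :, b].ravel(), ok,
                                  (f"hour {a}", f"hour {b}"))
        rs = []
        for p in range(cube.shape[0]):
            ok = obs[p, :, a] & obs[p, :, b]
            rs.append(_pairwise_corr(cube[p, :, a], cube[p, :, b], ok,
                                     (f"hour {a}", f"hour {b}")))
        return min(rs)

    groups: list[list[int]] = []
    corrs: list[list[float]] = []
    a = 0
    while a < 24:
        group = [a]
        gcorr: list[float] = []
        b = a + 1
        while b < 24:
            r = merge_corr(a, b)
            if r >= tau:
                group.append(b)
                gcorr.append(r)
                b += 1
            else:
                break
        groups.append(group)
        corrs.append(gcorr)
        a = group[-1] + 1
    return AggregationPlan(tau=tau, hour_groups=groups, hour_correlations=corrs)


def apply_hour_aggregation(raw: RawPNSD, plan: AggregationPlan) -> PNSDMatrix:
    """Average concentrations within each (day, hour-group).

    A reduced time step is the mean over the group's non-missing hours and is
    missing only when all member hours are missing.  The reduced time stamp
    is the day plus the group's first hour; ``block_labels`` records the
    within-day block index.
    """
    if plan.hour_groups is None:
        raise ValueError("plan has no hour groups")
    cube, obs, days = _day_hour_table(raw)
    P = raw.n_bins
    n_blocks = len(plan.hour_groups)
    T_new = len(days) * n_blocks
    values = np.full((P, T_new), np.nan)
    times = []
    blocks = np.empty(T_new, dtype=int)
    for d, day in enumerate(days):
        for b, g in enumerate(plan.hour_groups):
            t = d * n_blocks + b
            times.append(day + pd.Timedelta(hours=int(g[0])))
            blocks[t] = b
            chunk = cube[:, d, list(g)]
            any_obs = ~np.isnan(chunk).all(axis=1)
            values[any_obs, t] = np.nanmean(chunk[any_obs], axis=1)
    mask = np.isnan(values)
    # enforce column-wise missingness: a block is missing if any bin has no data
    col_any = mask.any(axis=0)
    mask[:, col_any] = True
    return PNSDMatrix(times=pd.DatetimeIndex(times), bin_labels=raw.bin_labels,
                      values=np.where(mask, 0, values), missing_mask=mask,
                      block_labels=blocks, bin_ranges=raw.bin_ranges)


def replace_zeros(m: PNSDMatrix) -> tuple[PNSDMatrix, int]:
    """Replace exact zeros by half the bin's minimum non-zero observed value.

    Zero concentrations are artifacts of values below the instrument's
    detection threshold; the true concentration is strictly positive.
    Returns the cleaned panel and the number of replacements.
    """
    values = m.values.copy()
    obs = ~m.missing_mask
    count = 0
    for p in range(m.n_bins):
        row = values[p]
        pos = obs[p] & (row > 0)
        zero = obs[p] & (row == 0)
        if not pos.any():
            raise ValueError(
                f"bin {m.bin_labels[p]:g} nm has no non-zero observed values"
            )
        if zero.any():
            row[zero] = row[pos].min() / 2.0
            count += int(zero.sum())
    out = PNSDMatrix(times=m.times, bin_labels=m.bin_labels, values=values,
                     missing_mask=m.missing_mask.copy(),
                     block_labels=m.block_labels.copy(), bin_ranges=m.bin_ranges)
    return out, count


def impute_covariates_mean(w: WindSeries, circular_direction: bool = False,
                           warn_above: float = 0.05) -> tuple[WindSeries, tuple[int, int]]:
    """Mean-impute missing wind speed and direction.

    Both covariates get the arithmetic mean of their observed values; for
    direction this is the plain mean of the degree values (the minimal
    reading of mean imputation), with ``circular_direction=True`` switching
    to the circular mean.  Returns the imputed series and the counts of
    imputed (speed, direction) entries.  Intended for small missing
    fractions; warns above ``warn_above``.
    """
    import warnings

    ws = w.ws.copy()
    wd = w.wd.copy()
    miss_ws = np.isnan(ws)
    miss_wd = np.isnan(wd)
    if miss_ws.all():
        raise ValueError("wind speed is entirely missing")
    if miss_wd.all():
        raise ValueError("wind direction is entirely missing")
    frac = max(miss_ws.mean(), miss_wd.mean())
    if frac > warn_above:
        warnings.warn(
            f"{100 * frac:.1f}% of wind observations are missing; "
            "mean imputation may be inappropriate", stacklevel=2)
    ws[miss_ws] = ws[~miss_ws].mean()
    if circular_direction:
        rad = np.deg2rad(wd[~miss_wd])
        mean_dir = _wrap360(
            np.rad2deg(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())))
        wd[miss_wd] = mean_dir
    else:
        wd[miss_wd] = wd[~miss_wd].mean()
    return WindSeries(ws=ws, wd=wd), (int(miss_ws.sum()), int(miss_wd.sum()))


def aggregate_wind_hours(times: pd.DatetimeIndex, wind: WindSeries,
                         plan: AggregationPlan) -> WindSeries:
    """Aggregate an hourly wind series to the plan's within-day blocks.

    Wind speed is averaged arithmetically; wind direction is averaged on the
    circle (vector mean), which is the standard convention for directional
    data.  Blocks with no observed hours come out as NaN.
    """
    if plan.hour_groups is None:
        raise ValueError("plan has no hour groups")
    carrier = RawPNSD(times=times, bin_labels=np.array([1.0]),
                      values=np.zeros((1, len(times))))
    _, _, days = _day_hour_table(carrier)
    dates = times.normalize()
    day_pos = pd.Series(np.arange(len(days)), index=days)
    di = day_pos.loc[dates].to_numpy()
    hi = times.hour.to_numpy()
    ws_cube = np.full((len(days), 24), np.nan)
    wd_cube = np.full((len(days), 24), np.nan)
    ws_cube[di, hi] = wind.ws
    wd_cube[di, hi] = wind.wd
    nb = len(plan.hour_groups)
    ws_out = np.empty(len(days) * nb)
    wd_out = np.empty(len(days) * nb)
    for d in range(len(days)):
        for b, g in enumerate(plan.hour_groups):
            t = d * nb + b
            ws_grp = ws_cube[d, list(g)]
            wd_grp = wd_cube[d, list(g)]
            ok_ws, ok_wd = ~np.isnan(ws_grp), ~np.isnan(wd_grp)
            ws_out[t] = ws_grp[ok_ws].mean() if ok_ws.any() else np.nan
            if ok_wd.any():
                rad = np.deg2rad(wd_grp[ok_wd])
                wd_out[t] = _wrap360(np.rad2deg(np.arctan2(
                    np.sin(rad).mean(), np.cos(rad).mean())))
            else:
                wd_out[t] = np.nan
    return WindSeries(ws=ws_out, wd=wd_out)


def reduction_summary(n_times_raw: int, n_bins_raw: int,
                      n_times_reduced: int, n_bins_reduced: int) -> dict:
    """Cell counts before/after reduction and the percent reduction (0.1% precision)."""
    before = n_times_raw * n_bins_raw
    after = n_times_reduced * n_bins_reduced
    return {
        "cells_before": before,
        "cells_after": after,
        "percent_reduction": round(100.0 * (1.0 - after / before), 1),
    }
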