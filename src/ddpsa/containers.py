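"""Core data containers shared across the pipeline.

The pipeline moves a particle number size distribution (PNSD) panel through
three representations:

* :class:`RawPNSD` — the hourly panel as measured (size bins × hours),
* :class:`PNSDMatrix` — the model-ready panel after bin/hour aggregation and
  zero replacement (aggregated bins × within-day blocks),
* :class:`WindSeries` — wind speed/direction covariates aligned to either
  time axis.

:class:`AggregationPlan` records how bins and hours were merged so the
reduction is auditable and replayable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawPNSD",
    "PNSDMatrix",
    "WindSeries",
    "AggregationPlan",
]


def _as_bool_mask(mask, shape) -> np.ndarray:
    if mask is None:
        return np.zeros(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"missing_mask shape {mask.shape} != values shape {shape}")
    return mask


@dataclass
class RawPNSD:
    """Hourly particle concentration panel, rows = size bins, cols = hours.

    Parameters
    ----------
    times : pandas.DatetimeIndex
        Hourly timestamps, strictly increasing, no duplicates.
    bin_labels : ndarray of float
        Particle size midpoints in nm, strictly increasing.
    values : ndarray, shape (P, T)
        Concentrations in particles/cm³, nonnegative where observed.
    missing_mask : ndarray of bool, shape (P, T)
        True where the measurement is missing.
    bin_ranges : list of (float, float), optional
        For aggregated panels, the (low, high) nm endpoints of each bin.
    """

    times: pd.DatetimeIndex
    bin_labels: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = None
    bin_ranges: list | None = None

    def __post_init__(self):
        self.times = pd.DatetimeIndex(self.times)
        self.bin_labels = np.asarray(self.bin_labels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (bins × times)")
        P, T = self.values.shape
        if len(self.bin_labels) != P:
            raise ValueError("bin_labels length does not match number of rows")
        if len(self.times) != T:
            raise ValueError("times length does not match number of columns")
        if self.times.has_duplicates:
            raise ValueError("duplicate time stamps")
        if P > 1 and not np.all(np.diff(self.bin_labels) > 0):
            raise ValueError("bin_labels must be strictly increasing")
        self.missing_mask = _as_bool_mask(self.missing_mask, self.values.shape)
        obs = ~self.missing_mask
        if np.any(self.values[obs] < 0):
            raise ValueError("observed concentrations must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]


@dataclass
class PNSDMatrix:
    """Model-ready concentration panel on the reduced (day × block) time axis.

    Missingness is column-wise: instrument downtime affects all size bins
    simultaneously, so a time step is either fully observed or fully missing.
    """

    times: pd.DatetimeIndex
    bin_labels: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = None
    block_labels: np.ndarray = None
    bin_ranges: list | None = None

    def __post_init__(self):
        self.times = pd.DatetimeIndex(self.times)
        self.bin_labels = np.asarray(self.bin_labels, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        P, T = self.values.shape
        if len(self.bin_labels) != P or len(self.times) != T:
            raise ValueError("inconsistent panel dimensions")
        self.missing_mask = _as_bool_mask(self.missing_mask, self.values.shape)
        if self.block_labels is None:
            self.block_labels = np.zeros(T, dtype=int)
        else:
            self.block_labels = np.asarray(self.block_labels, dtype=int)
            if len(self.block_labels) != T:
                raise ValueError("block_labels length does not match time axis")
        col_missing = self.missing_mask.any(axis=0)
        col_full = self.missing_mask.all(axis=0)
        if np.any(col_missing & ~col_full):
            raise ValueError("missingness must be column-wise (whole time steps)")

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def missing_cols(self) -> np.ndarray:
        """Boolean vector marking fully missing time steps."""
        return self.missing_mask.all(axis=0)

    @property
    def weekday(self) -> np.ndarray:
        return self.times.weekday.to_numpy()

    @property
    def month(self) -> np.ndarray:
        return self.times.month.to_numpy()

    def require_positive(self) -> None:
        obs = ~self.missing_mask
        if np.any(self.values[obs] <= 0):
            raise ValueError(
                "panel contains non-positive observed values; run replace_zeros first"
            )


@dataclass
class WindSeries:
    """Wind covariates: speed in m/s, direction in degrees clockwise from north."""

    ws: np.ndarray
    wd: np.ndarray

    def __post_init__(self):
        self.ws = np.asarray(self.ws, dtype=float)
        self.wd = np.asarray(self.wd, dtype=float)
        if self.ws.shape != self.wd.shape or self.ws.ndim != 1:
            raise ValueError("ws and wd must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.ws)

    @property
    def n_missing(self) -> tuple[int, int]:
        return int(np.isnan(self.ws).sum()), int(np.isnan(self.wd).sum())

    def validate(self) -> "WindSeries":
        """Check the invariants required for modelling (no NaN, valid ranges)."""
        if np.isnan(self.ws).any() or np.isnan(self.wd).any():
            raise ValueError("wind series contains missing values; impute first")
        if np.any(self.ws < 0):
            raise ValueError("wind speed must be nonnegative")
        if np.any((self.wd < 0) | (self.wd >= 360)):
            raise ValueError("wind direction must lie in [0, 360)")
        return self


@dataclass
class AggregationPlan:
    """Partition of size bins and/or hours of day into contiguous groups.

    ``tau`` is the Pearson-correlation threshold used by the greedy planner;
    ``bin_correlations`` / ``hour_correlations`` record the per-merge anchor
    correlations for audit.
    """

    tau: float
    bin_groups: list | None = None
    hour_groups: list | None = None
    bin_correlations: list = field(default_factory=list)
    hour_correlations: list = field(default_factory=list)

    def __post_init__(self):
        if not (0 <= self.tau) or not np.isfinite(self.tau):
            raise ValueError("tau must be a finite nonnegative threshold")
        for groups, n in ((self.bin_groups, None), (self.hour_groups, 24)):
            if groups is not None:
                _check_partition(groups, n)

    def to_json(self, path) -> None:
        payload = {
            "tau": self.tau,
            "bin_groups": self.bin_groups,
            "hour_groups": self.hour_groups,
            "bin_correlations": self.bin_correlations,
            "hour_correlations": self.hour_correlations,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "AggregationPlan":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tau=payload["tau"],
            bin_groups=payload.get("bin_groups"),
            hour_groups=payload.get("hour_groups"),
            bin_correlations=payload.get("bin_correlations") or [],
            hour_correlations=payload.get("hour_correlations") or [],
        )


def _check_partition(groups: Sequence[Sequence[int]], n: int | None) -> None:
    flat = [i for g in groups for i in g]
    if not flat:
        raise ValueError("empty partition")
    expected = list(range(max(flat) + 1 if n is None else n))
    if sorted(flat) != expected:
        raise ValueError("groups must be a non-overlapping cover of all indices")
    for g in groups:
        lst = list(g)
        if lst != list(range(lst[0], lst[-1] + 1)):
            raise ValueError("groups must be contiguous runs")
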