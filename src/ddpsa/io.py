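"""CSV readers/writers for concentration panels, wind and pollutant series.

Dialects: a PNSD file is wide, first column ``time`` (ISO-8601), remaining
columns named by the bin midpoint in nm, missing cells empty; a reduced
(model-ready) file additionally carries a ``block`` column with the
within-day block index.  A wind file has columns ``time, ws, wd``; a
pollutant file ``time`` plus one column per pollutant.
"""

from __future__ import annotations

import hashlib

import numpy as np
import pandas as pd

from .containers import PNSDMatrix, RawPNSD, WindSeries

__all__ = [
    "read_raw_csv",
    "write_raw_csv",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_wind_csv",
    "write_wind_csv",
    "read_pollutants_csv",
    "sha256sum",
]


def _fmt_bin(b: float) -> str:
    return f"{b:.6g}"


def read_raw_csv(path) -> tuple[RawPNSD, pd.DatetimeIndex]:
    df = pd.read_csv(path, parse_dates=["time"])
    times = pd.DatetimeIndex(df.pop("time"))
    bins = np.array([float(c) for c in df.columns])
    values = df.to_numpy(dtype=float).T
    mask = np.isnan(values)
    return RawPNSD(times=times, bin_labels=bins,
                   values=np.where(mask, 0, values), missing_mask=mask), times


def write_raw_csv(raw: RawPNSD, path) -> None:
    vals = np.where(raw.missing_mask, np.nan, raw.values)
    df = pd.DataFrame(vals.T, columns=[_fmt_bin(b) for b in raw.bin_labels])
    df.insert(0, "time", raw.times.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)


def read_matrix_csv(path) -> PNSDMatrix:
    df = pd.read_csv(path, parse_dates=["time"])
    times = pd.DatetimeIndex(df.pop("time"))
    blocks = df.pop("block").to_numpy(dtype=int)
    bins = np.array([float(c) for c in df.columns])
    values = df.to_numpy(dtype=float).T
    mask = np.isnan(values)
    return PNSDMatrix(times=times, bin_labels=bins,
                      values=np.where(mask, 0, values), missing_mask=mask,
                      block_labels=blocks)


def write_matrix_csv(m: PNSDMatrix, path) -> None:
    vals = np.where(m.missing_mask, np.nan, m.values)
    df = pd.DataFrame(vals.T, columns=[_fmt_bin(b) for b in m.bin_labels])
    df.insert(0, "block", m.block_labels)
    df.insert(0, "time", m.times.strftime("%Y-%m-%dT%H:%M:%S"))
    df.to_csv(path, index=False)


def read_wind_csv(path) -> tuple[WindSeries, pd.DatetimeIndex]:
    df = pd.read_csv(path, parse_dates=["time"])
    return (WindSeries(ws=df["ws"].to_numpy(dtype=float),
                       wd=df["wd"].to_numpy(dtype=float)),
            pd.DatetimeIndex(df["time"]))


def write_wind_csv(wind: WindSeries, times: pd.DatetimeIndex, path) -> None:
    pd.DataFrame({"time": times.strftime("%Y-%m-%dT%H:%M:%S"),
                  "ws": wind.ws, "wd": wind.wd}).to_csv(path, index=False)


def read_pollutants_csv(path) -> tuple[pd.DataFrame, pd.DatetimeIndex]:
    df = pd.read_csv(path, parse_dates=["time"])
    times = pd.DatetimeIndex(df.pop("time"))
    return df, times


def sha256sum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
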