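"""Localization tables and their processing.

A :class:`LocalizationTable` wraps a pandas DataFrame of per-blink records
(``frame, x_nm, y_nm, photons`` and optional ``precision_nm``) with acquisition
metadata (seconds per frame, camera pixel size, total frame count). Processing
steps — photon filtering, fiducial-based drift correction, channel
registration, circular region picks and 2-D rendering — conserve or reduce the
record count; no stage invents localizations.

I/O covers headered CSV and Picasso-style HDF5 (``locs`` dataset with
``frame, x, y, photons, lpx, lpy`` in camera pixels, converted via
``pixel_nm``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import InsufficientFiducialsError, ParameterError, RegistrationError

__all__ = [
    "LocalizationTable",
    "PickRegion",
    "read_locs_csv",
    "write_locs_csv",
    "read_locs_hdf5",
    "write_locs_hdf5",
    "filter_photons",
    "drift_correct",
    "register_channels",
    "pick_circle",
    "render_histogram",
]

DEFAULT_FRAME_TIME_S = 0.1  # 100 ms exposure
DEFAULT_PIXEL_NM = 159.0    # 3.18 um pick = 20 camera pixels
DEFAULT_N_FRAMES = 20000

_REQUIRED = ("frame", "x_nm", "y_nm", "photons")


@dataclass
class LocalizationTable:
    """Per-blink localization records from one imaging channel."""

    df: pd.DataFrame
    frame_time_s: float = DEFAULT_FRAME_TIME_S
    pixel_nm: float = DEFAULT_PIXEL_NM
    n_frames: int | None = None

    def __post_init__(self):
        missing = [c for c in _REQUIRED if c not in self.df.columns]
        if missing:
            raise ParameterError(f"localization table missing columns {missing}")
        if len(self.df):
            if (self.df["frame"] < 0).any():
                raise ParameterError("negative frame index in localization table")
            if (self.df["photons"] <= 0).any():
                raise ParameterError("non-positive photon count in localization table")
        if self.n_frames is None:
            self.n_frames = int(self.df["frame"].max()) + 1 if len(self.df) else 0

    def __len__(self) -> int:
        return len(self.df)

    def with_df(self, df: pd.DataFrame) -> "LocalizationTable":
        return replace(self, df=df.reset_index(drop=True))

    def sorted_by_frame(self) -> "LocalizationTable":
        return self.with_df(self.df.sort_values("frame", kind="mergesort"))


@dataclass(frozen=True)
class PickRegion:
    """Circular analysis region (center in nm; default 3.18 um diameter)."""

    center: tuple
    diameter: float = 3180.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise ParameterError("pick diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


# ---------------------------------------------------------------- I/O

def read_locs_csv(path, frame_time_s: float = DEFAULT_FRAME_TIME_S,
                  pixel_nm: float = DEFAULT_PIXEL_NM,
                  n_frames: int | None = None) -> LocalizationTable:
    df = pd.read_csv(path)
    return LocalizationTable(df, frame_time_s, pixel_nm, n_frames)


def write_locs_csv(table: LocalizationTable, path) -> None:
    cols = [c for c in ("frame", "x_nm", "y_nm", "photons", "precision_nm")
            if c in table.df.columns]
    table.df.to_csv(path, index=False, columns=cols)


def read_locs_hdf5(path, frame_time_s: float = DEFAULT_FRAME_TIME_S,
                   pixel_nm: float = DEFAULT_PIXEL_NM,
                   n_frames: int | None = None) -> LocalizationTable:
    """Read a Picasso-style HDF5 file (x/y/lpx/lpy in camera pixels)."""
    with h5py.File(path, "r") as fh:
        locs = fh["locs"][()]
    df = pd.DataFrame({
        "frame": locs["frame"].astype(np.int64),
        "x_nm": locs["x"] * pixel_nm,
        "y_nm": locs["y"] * pixel_nm,
        "photons": locs["photons"],
    })
    if "lpx" in locs.dtype.names and "lpy" in locs.dtype.names:
        df["precision_nm"] = 0.5 * (locs["lpx"] + locs["lpy"]) * pixel_nm
    return LocalizationTable(df, frame_time_s, pixel_nm, n_frames)


def write_locs_hdf5(table: LocalizationTable, path) -> None:
    df = table.df
    prec = (df["precision_nm"].to_numpy() if "precision_nm" in df.columns
            else np.zeros(len(df)))
    rec = np.rec.fromarrays(
        [
            df["frame"].to_numpy(np.int64),
            df["x_nm"].to_numpy() / table.pixel_nm,
            df["y_nm"].to_numpy() / table.pixel_nm,
            df["photons"].to_numpy(),
            prec / table.pixel_nm,
            prec / table.pixel_nm,
        ],
        names="frame,x,y,photons,lpx,lpy",
    )
    with h5py.File(path, "w") as fh:
        fh.create_dataset("locs", data=rec)


# ---------------------------------------------------------------- processing

def filter_photons(table: LocalizationTable, lo: float = 420.0,
                   hi: float = 10000.0) -> LocalizationTable:
    """Keep records with ``lo <= photons <= hi`` (both bounds inclusive)."""
    if not lo < hi:
        raise ParameterError(f"photon window requires lo < hi, got [{lo}, {hi}]")
    df = table.df
    return table.with_df(df[(df["photons"] >= lo) & (df["photons"] <= hi)])


def _fiducial_displacement(fid: LocalizationTable, n_frames: int) -> np.ndarray:
    """Per-frame (dx, dy) of one fiducial relative to its first localization,
    linearly interpolated over frames it missed. NaN outside its span."""
    df = fid.df.sort_values("frame")
    frames = df["frame"].to_numpy(np.int64)
    x = df["x_nm"].to_numpy(float)
    y = df["y_nm"].to_numpy(float)
    # average duplicates within a frame
    uf, inv = np.unique(frames, return_inverse=True)
    xs = np.bincount(inv, weights=x) / np.bincount(inv)
    ys = np.bincount(inv, weights=y) / np.bincount(inv)
    out = np.full((n_frames, 2), np.nan)
    grid = np.arange(uf[0], uf[-1] + 1)
    out[grid, 0] = np.interp(grid, uf, xs - xs[0])
    out[grid, 1] = np.interp(grid, uf, ys - ys[0])
    return out


def _moving_average(a: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average ignoring NaNs, edge-aware."""
    n = len(a)
    out = np.empty(n)
    isnan = np.isnan(a)
    vals = np.where(isnan, 0.0, a)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cnt = np.concatenate([[0], np.cumsum(~isnan)])
    half = window // 2
    lo = np.clip(np.arange(n) - half, 0, n)
    hi = np.clip(np.arange(n) + half + 1, 0, n)
    num = csum[hi] - csum[lo]
    den = cnt[hi] - cnt[lo]
    with np.errstate(invalid="ignore"):
        out = np.where(den > 0, num / np.maximum(den, 1), 0.0)
    return out


def drift_correct(table: LocalizationTable, fiducials,
                  window: int = 200, min_coverage: float = 0.5):
    """Fiducial-based drift correction.

    The per-frame drift is the across-fiducial mean displacement from each
    fiducial's first-frame position, smoothed with a centered ``window``-frame
    moving average (default 200 frames: suppresses few-nm localization noise
    while tracking slow mechanical drift). The smoothed track is subtracted
    from every record. Returns ``(corrected_table, drift)`` with ``drift`` a
    DataFrame of frame, dx_nm, dy_nm.
    """
    n_frames = table.n_frames or (int(table.df["frame"].max()) + 1 if len(table.df) else 0)
    for fid in fiducials:
        if len(fid.df):
            n_frames = max(n_frames, int(fid.df["frame"].max()) + 1)
    usable = []
    for fid in fiducials:
        if not len(fid.df):
            continue
        span = fid.df["frame"].nunique()
        if span >= min_coverage * n_frames:
            usable.append(_fiducial_displacement(fid, n_frames))
    if not usable:
        raise InsufficientFiducialsError(
            f"no fiducial track covers >= {min_coverage:.0%} of {n_frames} frames"
        )
    disp = np.nanmean(np.stack(usable), axis=0)  # (n_frames, 2)
    drift = np.column_stack([
        _moving_average(disp[:, 0], window),
        _moving_average(disp[:, 1], window),
    ])
    # re-anchor at the *smoothed* start: referencing raw first-frame
    # localizations would bake their noise in as a constant offset
    drift -= drift[0]
    frames = table.df["frame"].to_numpy(np.int64)
    df = table.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy() - drift[frames, 0]
    df["y_nm"] = df["y_nm"].to_numpy() - drift[frames, 1]
    track = pd.DataFrame({
        "frame": np.arange(n_frames),
        "dx_nm": drift[:, 0],
        "dy_nm": drift[:, 1],
    })
    return table.with_df(df), track


def apply_drift(table: LocalizationTable, track: pd.DataFrame) -> LocalizationTable:
    """Subtract a previously computed drift track (e.g. on a second channel)."""
    frames = table.df["frame"].to_numpy(np.int64)
    drift = track[["dx_nm", "dy_nm"]].to_numpy()
    df = table.df.copy()
    df["x_nm"] = df["x_nm"].to_numpy() - drift[frames, 0]
    df["y_nm"] = df["y_nm"].to_numpy() - drift[frames, 1]
    return table.with_df(df)


def register_channels(fids_a, fids_b) -> tuple:
    """Translation (dx, dy) of channel B relative to A from matched fiducials.

    The mean pairwise displacement is the least-squares translation; subtract
    it from channel B to align. Requires >= 2 matched pairs.
    """
    a = np.asarray(fids_a, float)
    b = np.asarray(fids_b, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2 or a.shape[1] != 2:
        raise RegistrationError(
            f"need >= 2 matched (x, y) fiducial pairs, got shapes {a.shape} vs {b.shape}"
        )
    d = (b - a).mean(axis=0)
    return float(d[0]), float(d[1])


def pick_circle(table: LocalizationTable, pick: PickRegion) -> LocalizationTable:
    """Records within the pick circle (boundary inclusive)."""
    dx = table.df["x_nm"].to_numpy() - pick.center[0]
    dy = table.df["y_nm"].to_numpy() - pick.center[1]
    keep = dx * dx + dy * dy <= pick.radius ** 2
    return table.with_df(table.df[keep])


def render_histogram(table: LocalizationTable, bin_nm: float = 16.0):
    """2-D localization count grid at ``bin_nm`` resolution.

    Returns ``(grid, x_edges, y_edges)``; the grid total equals the record
    count.
    """
    if bin_nm <= 0:
        raise ParameterError("bin_nm must be > 0")
    x = table.df["x_nm"].to_numpy(float)
    y = table.df["y_nm"].to_numpy(float)
    if len(x) == 0:
        return np.zeros((0, 0)), np.zeros(1), np.zeros(1)
    x0, x1 = x.min(), x.max()
    y0, y1 = y.min(), y.max()
    nx = max(1, int(np.ceil((x1 - x0) / bin_nm)))
    ny = max(1, int(np.ceil((y1 - y0) / bin_nm)))
    grid, xe, ye = np.histogram2d(
        x, y, bins=[nx, ny],
        range=[[x0, x0 + nx * bin_nm], [y0, y0 + ny * bin_nm]],
    )
    return grid, xe, ye
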