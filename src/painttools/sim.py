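"""Synthetic localization data with known ground truth.

Imager binding at each docking site is an alternating renewal process: dark
dwells are exponential with mean ``1/xi`` (``xi = k_on * c``) and bright
dwells exponential with mean ``tau_bright_s``. Bright intervals are rasterized
onto camera frames (a site is bright in a frame when the interval covers at
least half the frame time, which makes event durations reproducible); every
bright frame yields one localization at the site position plus Gaussian
localization noise plus the cumulative stage drift at that frame. Photon
counts are lognormal (median 2000, sigma_log 0.5) so the standard 420-10,000
photon filter is exercised with realistic tails.

Defaults emulate a typical acquisition: 20,000 frames at 100 ms, localization
noise 8 nm. All generators are deterministic under their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import LayoutError, ParameterError
from .locs import DEFAULT_FRAME_TIME_S, DEFAULT_N_FRAMES, LocalizationTable, PickRegion
from .qpaint import KineticParams, influx_rate

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_blinking",
    "simulate_fiducials",
    "simulate_scene",
    "random_srna",
]


@dataclass(frozen=True)
class SimConfig:
    """Scene and kinetics parameters for one simulated channel.

    ``layout`` is "point" (sites scattered tightly around ``center`` with
    ``cluster_sigma_nm``) or "circle" (uniform within ``radius_nm`` of
    ``center``).
    """

    n_sites: int = 10
    kinetics: KineticParams = field(default_factory=KineticParams)
    layout: str = "circle"
    center: tuple = (0.0, 0.0)
    radius_nm: float = 1590.0
    cluster_sigma_nm: float = 50.0
    n_frames: int = DEFAULT_N_FRAMES
    frame_time_s: float = DEFAULT_FRAME_TIME_S
    loc_sigma_nm: float = 8.0
    drift_nm_per_frame: tuple = (0.0, 0.0)
    photon_median: float = 2000.0
    photon_sigma_log: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_sites < 0 or self.n_frames < 1:
            raise ParameterError("need n_sites >= 0 and n_frames >= 1")
        if self.layout not in ("point", "circle"):
            raise ParameterError(f"layout must be 'point' or 'circle', got {self.layout!r}")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated table: site positions (nm),
    per-site (t_on, t_off) event lists, and the kinetics used."""

    site_positions: np.ndarray
    events_per_site: list
    n_sites: int
    kinetics: KineticParams
    region_counts: list = field(default_factory=list)


def _site_positions(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.n_sites == 0:
        return np.zeros((0, 2))
    cx, cy = cfg.center
    if cfg.layout == "point":
        return np.column_stack([
            rng.normal(cx, cfg.cluster_sigma_nm, cfg.n_sites),
            rng.normal(cy, cfg.cluster_sigma_nm, cfg.n_sites),
        ])
    r = cfg.radius_nm * np.sqrt(rng.uniform(0, 1, cfg.n_sites))
    th = rng.uniform(0, 2 * math.pi, cfg.n_sites)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


def _bright_intervals(xi: float, tau_bright: float, t_total: float,
                      rng: np.random.Generator) -> list:
    """Alternating dark/bright renewal process truncated at t_total."""
    out = []
    t = 0.0
    while True:
        t += rng.exponential(1.0 / xi)
        if t >= t_total:
            return out
        dur = rng.exponential(tau_bright)
        out.append((t, min(t + dur, t_total)))
        t += dur
        if t >= t_total:
            return out


def _raster_frames(a: float, b: float, dt: float, n_frames: int) -> range:
    """Frames whose overlap with [a, b) is at least half a frame."""
    f0 = max(0, int(math.floor(a / dt)))
    f1 = min(n_frames - 1, int(math.ceil(b / dt)))
    lo = None
    hi = None
    for f in range(f0, f1 + 1):
        overlap = min(b, (f + 1) * dt) - max(a, f * dt)
        if overlap >= 0.5 * dt:
            if lo is None:
                lo = f
            hi = f
    return range(lo, hi + 1) if lo is not None else range(0)


def simulate_blinking(cfg: SimConfig) -> tuple:
    """Simulate one channel of imager-binding blinking.

    Returns ``(LocalizationTable, SimTruth)``. Localizations from different
    sites are not merged spatially — sites are treated as resolvable — but
    they share frames, which is exactly the regime qPAINT's kinetics-only
    counting is built for.
    """
    rng = np.random.default_rng(cfg.seed)
    xi = influx_rate(cfg.kinetics)
    t_total = cfg.n_frames * cfg.frame_time_s
    sites = _site_positions(cfg, rng)
    frames, xs, ys = [], [], []
    events_per_site = []
    for s in range(cfg.n_sites):
        intervals = _bright_intervals(xi, cfg.kinetics.tau_bright_s, t_total, rng)
        events_per_site.append(intervals)
        for a, b in intervals:
            for f in _raster_frames(a, b, cfg.frame_time_s, cfg.n_frames):
                frames.append(f)
                xs.append(sites[s, 0])
                ys.append(sites[s, 1])
    frames = np.asarray(frames, np.int64)
    n = len(frames)
    order = np.argsort(frames, kind="stable")
    frames = frames[order]
    xs = np.asarray(xs)[order]
    ys = np.asarray(ys)[order]
    drift = np.outer(np.arange(cfg.n_frames), np.asarray(cfg.drift_nm_per_frame, float))
    noise = rng.normal(0.0, cfg.loc_sigma_nm, (n, 2))
    photons = rng.lognormal(math.log(cfg.photon_median), cfg.photon_sigma_log, n)
    df = pd.DataFrame({
        "frame": frames,
        "x_nm": xs + noise[:, 0] + drift[frames, 0],
        "y_nm": ys + noise[:, 1] + drift[frames, 1],
        "photons": photons,
        "precision_nm": np.full(n, cfg.loc_sigma_nm),
    })
    table = LocalizationTable(df, cfg.frame_time_s, n_frames=cfg.n_frames)
    truth = SimTruth(sites, events_per_site, cfg.n_sites, cfg.kinetics)
    return table, truth


def simulate_fiducials(n: int, drift_nm_per_frame=(0.0, 0.0), noise_nm: float = 5.0,
                       n_frames: int = DEFAULT_N_FRAMES, seed: int = 0,
                       extent_nm: float = 20000.0,
                       frame_time_s: float = DEFAULT_FRAME_TIME_S) -> list:
    """Fiducial tracks: fixed positions + cumulative drift + Gaussian noise,
    localized in every frame. Returns one LocalizationTable per fiducial."""
    if n < 1:
        raise ParameterError("need at least one fiducial")
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, extent_nm, (n, 2))
    drift = np.outer(np.arange(n_frames), np.asarray(drift_nm_per_frame, float))
    out = []
    for i in range(n):
        noise = rng.normal(0.0, noise_nm, (n_frames, 2)) if noise_nm > 0 else np.zeros((n_frames, 2))
        df = pd.DataFrame({
            "frame": np.arange(n_frames, dtype=np.int64),
            "x_nm": pos[i, 0] + drift[:, 0] + noise[:, 0],
            "y_nm": pos[i, 1] + drift[:, 1] + noise[:, 1],
            "photons": np.full(n_frames, 5000.0),
        })
        out.append(LocalizationTable(df, frame_time_s, n_frames=n_frames))
    return out


def simulate_scene(regions, cfg: SimConfig) -> tuple:
    """Union of independent per-region simulations with disjointness checked.

    ``regions`` is a list of ``(PickRegion, n_sites)``; sites are uniform in
    each region's circle. The returned truth records per-region counts.
    """
    regs = list(regions)
    for i in range(len(regs)):
        for j in range(i + 1, len(regs)):
            a, b = regs[i][0], regs[j][0]
            d = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if d < a.radius + b.radius:
                raise LayoutError(f"regions {i} and {j} overlap (centers {d:.0f} nm apart)")
    tables = []
    all_sites = []
    all_events = []
    counts = []
    for i, (region, n_sites) in enumerate(regs):
        sub = replace(cfg, n_sites=int(n_sites), layout="circle",
                      center=tuple(region.center), radius_nm=region.radius,
                      seed=cfg.seed + i)
        t, tr = simulate_blinking(sub)
        tables.append(t.df)
        all_sites.append(tr.site_positions)
        all_events.extend(tr.events_per_site)
        counts.append(int(n_sites))
    if tables:
        df = pd.concat(tables, ignore_index=True).sort_values(
            "frame", kind="mergesort").reset_index(drop=True)
    else:
        df = pd.DataFrame({"frame": [], "x_nm": [], "y_nm": [], "photons": []})
    table = LocalizationTable(df, cfg.frame_time_s, n_frames=cfg.n_frames)
    sites = np.vstack(all_sites) if all_sites else np.zeros((0, 2))
    truth = SimTruth(sites, all_events, int(sites.shape[0]), cfg.kinetics,
                     region_counts=counts)
    return table, truth


def random_srna(length: int, gc_fraction: float = 0.5, seed: int = 0) -> str:
    """A random RNA-alphabet target of the small-RNA size class (21-24 nt
    typical) with the requested expected GC content."""
    if not 0 <= gc_fraction <= 1:
        raise ParameterError("gc_fraction must be in [0, 1]")
    if length < 1:
        raise ParameterError("length must be >= 1")
    rng = np.random.default_rng(seed)
    p = [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    return "".join(rng.choice(list("AGCU"), size=length, p=p))
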