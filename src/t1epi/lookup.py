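"""Lookup-table T1 quantification.

The forward Bloch model maps T1 to a per-voxel signal statistic — by default
the signed ratio ``S1/S2`` of the two inversion-time signals, alternatively
the UNI statistic.  Tabulating the statistic over a T1 grid at several
transmit-field (B1) scales, and restricting each curve to its strictly
monotone branch, gives an invertible map from measured statistic to T1 in
milliseconds.  Local flip-angle deviations are handled to first order by a
per-voxel B1 scale from a template map: inversion is performed on the two
tabulated B1 curves bracketing the local scale and interpolated linearly.
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import zoom as _ndzoom
from scipy.stats import gaussian_kde

from .bloch import signal_arrays
from .config import ProtocolConfig
from .io import ImageVolume

logger = logging.getLogger("t1epi")

__all__ = [
    "LookupTable",
    "B1Map",
    "T1Map",
    "FLAG_IN_RANGE",
    "FLAG_CLAMPED_LOW",
    "FLAG_CLAMPED_HIGH",
    "FLAG_NO_SIGNAL",
    "build_lookup_table",
    "invert_lookup",
    "estimate_t1_map",
    "histogram_peaks",
    "voxel_statistic",
]

FLAG_IN_RANGE = 0
FLAG_CLAMPED_LOW = 1
FLAG_CLAMPED_HIGH = 2
FLAG_NO_SIGNAL = 3


@dataclass(frozen=True)
class B1Map:
    """Relative transmit-field scale per voxel (1 = nominal flip angle)."""

    data: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.data, dtype=float)
        if np.any(d[np.isfinite(d)] < 0):
            raise ValueError("B1 scale must be positive where defined")
        object.__setattr__(self, "data", d)


@dataclass(frozen=True)
class T1Map:
    """Voxelwise T1 (ms) plus per-voxel validity flags."""

    T1: np.ndarray  # ms; NaN where no signal
    flags: np.ndarray  # FLAG_* codes

    @property
    def in_range(self) -> np.ndarray:
        return self.flags == FLAG_IN_RANGE


@dataclass(frozen=True)
class LookupTable:
    """Monotone map between a two-TI signal statistic and T1, per B1 scale.

    ``values[i, j]`` is the statistic at ``t1_grid[j]`` and ``b1_grid[i]``;
    ``valid[i]`` is the (start, stop) slice of the strictly monotone branch
    used for inversion at that B1.
    """

    t1_grid: np.ndarray  # ms, strictly increasing
    b1_grid: np.ndarray  # relative, strictly increasing
    values: np.ndarray  # shape (n_b1, n_t1)
    valid: Tuple[Tuple[int, int], ...]
    statistic: str
    protocol_hash: str
    meta: dict = field(default_factory=dict)

    def valid_t1_range(self, i_b1: int = 0) -> Tuple[float, float]:
        lo, hi = self.valid[i_b1]
        return float(self.t1_grid[lo]), float(self.t1_grid[hi - 1])

    def to_csv(self, path: Path | str) -> Path:
        path = Path(path)
        buf = _io.StringIO()
        buf.write(f"# statistic = {self.statistic}\n")
        buf.write(f"# protocol_hash = {self.protocol_hash}\n")
        for k, v in self.meta.items():
            buf.write(f"# {k} = {v}\n")
        df = pd.DataFrame(self.values.T, index=self.t1_grid,
                          columns=[f"b1={b:g}" for b in self.b1_grid])
        df.index.name = "T1_ms"
        df.to_csv(buf)
        path.write_text(buf.getvalue())
        return path


def _protocol_hash(p: ProtocolConfig) -> str:
    return hashlib.sha256(p.model_dump_json().encode()).hexdigest()[:16]


def _statistic_from_signals(s1, s2, kind: str):
    if kind == "ratio":
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(s2 != 0, s1 / np.where(s2 != 0, s2, 1.0), np.nan)
    if kind == "uni":
        den = s1 * s1 + s2 * s2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, s1 * s2 / np.where(den > 0, den, 1.0), np.nan)
    raise ValueError(f"unknown statistic {kind!r}")


def _longest_monotone_run(y: np.ndarray) -> Tuple[int, int]:
    """(start, stop) of the longest strictly monotone, finite run of y."""
    n = len(y)
    best = (0, 1)
    start = 0
    sign = 0
    for k in range(1, n):
        d = y[k] - y[k - 1]
        ok = np.isfinite(y[k]) and np.isfinite(y[k - 1]) and d != 0
        s = np.sign(d) if ok else 0
        if not ok or (sign != 0 and s != sign):
            start, sign = k, 0
        else:
            if sign == 0:
                sign = s
            if k + 1 - start > best[1] - best[0]:
                best = (start, k + 1)
    return best


def build_lookup_table(
    p: ProtocolConfig,
    t1_min: float = 300.0,
    t1_max: float = 5000.0,
    t1_step: float = 10.0,
    b1_grid: Sequence[float] | None = None,
    statistic: str = "ratio",
) -> LookupTable:
    """Tabulate the signal statistic over (T1, B1) from the Bloch model.

    Each B1 curve is restricted to its longest strictly monotone branch; if
    trimming occurs it is logged, and an empty branch raises.
    """
    if not 0 < t1_min < t1_max <= 10000:
        raise ValueError("T1 range must lie within (0, 10000] ms")
    t1 = np.arange(t1_min, t1_max + 0.5 * t1_step, t1_step)
    if b1_grid is None:
        b1_grid = np.round(np.arange(0.6, 1.4001, 0.02), 3)
    b1 = np.asarray(sorted(b1_grid), dtype=float)
    vals = np.empty((len(b1), len(t1)))
    valid = []
    for i, bscale in enumerate(b1):
        s1, s2 = signal_arrays(p, t1, 1.0, bscale)
        vals[i] = _statistic_from_signals(s1, s2, statistic)
        lo, hi = _longest_monotone_run(vals[i])
        if hi - lo < 2:
            raise ValueError(f"statistic non-monotone everywhere at b1={bscale}")
        if (lo, hi) != (0, len(t1)):
            logger.info(
                "lookup: monotone branch at b1=%g trimmed to T1 in [%g, %g] ms",
                bscale, t1[lo], t1[hi - 1],
            )
        valid.append((lo, hi))
    return LookupTable(
        t1_grid=t1,
        b1_grid=b1,
        values=vals,
        valid=tuple(valid),
        statistic=statistic,
        protocol_hash=_protocol_hash(p),
        meta={"t1_step_ms": t1_step},
    )


def _invert_curve(y: np.ndarray, t: np.ndarray, lo: int, hi: int, stat: np.ndarray):
    """Monotone inversion of one statistic curve restricted to [lo, hi)."""
    y = y[lo:hi]
    t = t[lo:hi]
    increasing_t1 = True
    if y[0] > y[-1]:  # np.interp needs increasing x
        y, t = y[::-1], t[::-1]
        increasing_t1 = False
    t1 = np.interp(stat, y, t)
    flags = np.full(stat.shape, FLAG_IN_RANGE, dtype=np.int8)
    lo_clip = stat < y[0]
    hi_clip = stat > y[-1]
    # clamp flags follow the T1 axis, not the statistic axis
    if increasing_t1:
        flags[lo_clip] = FLAG_CLAMPED_LOW
        flags[hi_clip] = FLAG_CLAMPED_HIGH
    else:
        flags[lo_clip] = FLAG_CLAMPED_HIGH
        flags[hi_clip] = FLAG_CLAMPED_LOW
    return t1, flags


def invert_lookup(table: LookupTable, stat, b1=1.0, b1_resolution: float = 0.0005):
    """Convert statistic values to T1 (ms) with validity flags.

    NaN statistics map to the no-signal flag.  The local B1 scale is handled
    by linear interpolation between the two bracketing tabulated statistic
    curves (the interpolated curve is then inverted on the intersection of
    their monotone branches); B1 values are quantized to ``b1_resolution``
    to bound the number of interpolated curves.  Scales outside the table's
    B1 hull raise.  Scalar inputs return scalars.
    """
    stat_arr = np.atleast_1d(np.asarray(stat, dtype=float))
    b1_arr = np.broadcast_to(np.asarray(b1, dtype=float), stat_arr.shape)
    if np.any((b1_arr < table.b1_grid[0] - 1e-9) | (b1_arr > table.b1_grid[-1] + 1e-9)):
        raise ValueError("b1 outside the tabulated hull")
    nosig = ~np.isfinite(stat_arr)
    work = np.where(nosig, 0.0, stat_arr)

    bq = np.round(b1_arr / b1_resolution) * b1_resolution
    bq = np.clip(bq, table.b1_grid[0], table.b1_grid[-1])

    t1_out = np.zeros_like(work)
    flags = np.zeros(work.shape, dtype=np.int8)
    for bval in np.unique(bq):
        m = bq == bval
        i = int(np.clip(np.searchsorted(table.b1_grid, bval, side="right") - 1,
                        0, len(table.b1_grid) - 2))
        b_lo, b_hi = table.b1_grid[i], table.b1_grid[i + 1]
        w = (bval - b_lo) / (b_hi - b_lo)
        curve = (1 - w) * table.values[i] + w * table.values[i + 1]
        lo = max(table.valid[i][0], table.valid[i + 1][0])
        hi = min(table.valid[i][1], table.valid[i + 1][1])
        if hi - lo < 2:
            raise ValueError(f"no common monotone branch near b1={bval:g}")
        t1_out[m], flags[m] = _invert_curve(curve, table.t1_grid, lo, hi, work[m])
    t1_out[nosig] = np.nan
    flags[nosig] = FLAG_NO_SIGNAL
    if np.isscalar(stat) or np.asarray(stat).ndim == 0:
        return float(t1_out[0]), int(flags[0])
    return t1_out, flags


def voxel_statistic(vol1: np.ndarray, vol2: np.ndarray, kind: str = "ratio",
                    magnitude: bool = False) -> np.ndarray:
    """Per-voxel statistic from the two TI volumes.

    Complex inputs are combined phase-sensitively (``Re(S1 conj(S2)) /
    |S2|^2`` for the ratio), preserving the sign of the recovery; magnitude
    mode uses ``|S1|/|S2|`` and loses it.  Voxels with no signal give NaN.
    """
    v1 = np.asarray(vol1)
    v2 = np.asarray(vol2)
    if v1.shape != v2.shape:
        raise ValueError("TI1/TI2 volumes must be congruent")
    if magnitude:
        v1, v2 = np.abs(v1), np.abs(v2)
    if np.iscomplexobj(v1) or np.iscomplexobj(v2):
        if kind == "ratio":
            den = np.abs(v2) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                return np.where(den > 0, (v1 * np.conj(v2)).real / np.where(den > 0, den, 1.0), np.nan)
        den = np.abs(v1) ** 2 + np.abs(v2) ** 2
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den > 0, (np.conj(v1) * v2).real / np.where(den > 0, den, 1.0), np.nan)
    return _statistic_from_signals(v1.astype(float), v2.astype(float), kind)


def _resample_to(data: np.ndarray, shape) -> np.ndarray:
    if data.shape == tuple(shape):
        return data
    factors = [s / d for s, d in zip(shape, data.shape)]
    out = _ndzoom(data, factors, order=1, mode="nearest", grid_mode=True)
    if out.shape != tuple(shape):  # guard against rounding in ndimage
        out = out[tuple(slice(0, s) for s in shape)]
    return out


def estimate_t1_map(
    vol1: ImageVolume,
    vol2: ImageVolume,
    table: LookupTable,
    b1map: B1Map | None = None,
    magnitude: bool = False,
) -> T1Map:
    """Voxelwise T1 map from the two TI volumes via the lookup table.

    A low-resolution B1 template is resampled to the image grid by trilinear
    interpolation.  Voxels with zero signal are flagged no-signal and carry
    no T1 value; statistics beyond the monotone branch are clamped and
    flagged.
    """
    if vol1.shape != vol2.shape:
        raise ValueError("TI1/TI2 volumes must share a grid")
    stat = voxel_statistic(vol1.data, vol2.data, kind=table.statistic,
                           magnitude=magnitude)
    b1 = np.ones(stat.shape) if b1map is None else _resample_to(b1map.data, stat.shape)
    if b1.shape != stat.shape:
        raise ValueError("B1 map could not be resampled to the image grid")
    t1, flags = invert_lookup(table, stat, b1)
    return T1Map(T1=t1, flags=flags)


def histogram_peaks(t1map: T1Map, masks: dict, bandwidth: str | float = "scott",
                    grid_step: float = 5.0) -> dict:
    """Per-tissue modal T1 (ms) by Gaussian kernel density.

    ``masks`` maps tissue name to a boolean mask.  The mode is the argmax of
    a Gaussian KDE (Scott's rule by default) evaluated on a ``grid_step`` ms
    grid; exact ties break toward the lower T1.  Requires at least 100
    in-range voxels per tissue.
    """
    out = {}
    for name, mask in masks.items():
        vals = t1map.T1[mask & t1map.in_range]
        vals = vals[np.isfinite(vals)]
        if vals.size < 100:
            raise ValueError(f"tissue {name!r}: only {vals.size} in-range voxels (< 100)")
        if np.ptp(vals) == 0:
            out[name] = float(vals[0])
            continue
        kde = gaussian_kde(vals, bw_method=bandwidth)
        grid = np.arange(vals.min(), vals.max() + grid_step, grid_step)
        dens = kde(grid)
        # near-ties (within float noise of the max) break toward lower T1
        near = dens >= dens.max() * (1.0 - 1e-9)
        out[name] = float(grid[near][0])
    return out
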