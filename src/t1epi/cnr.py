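"""Flip-angle design by contrast-to-noise optimization.

The grey/white-matter contrast of the bias-cancelling UNI statistic
``UNI = S1*S2 / (S1^2 + S2^2)`` depends on the two excitation flip angles
through the steady-state signals.  Its noise is propagated to first order
(delta method) assuming independent additive Gaussian noise of equal
standard deviation on S1 and S2:

    sigma_UNI^2 = (dUNI/dS1)^2 sigma^2 + (dUNI/dS2)^2 sigma^2

and the design objective is

    CNR(a1, a2) = |UNI_GM - UNI_WM| / sqrt(sigma_UNI,GM^2 + sigma_UNI,WM^2)

maximized over a grid of flip-angle pairs, with a local quadratic refinement
around the grid argmax.  A raw signal-difference objective is available as an
alternative contrast statistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .bloch import SignalPair, signal_arrays
from .config import ProtocolConfig, TissueParams

__all__ = [
    "NoiseModel",
    "CNRSurface",
    "uni_statistic",
    "propagate_uni_noise",
    "cnr_surface",
    "optimize_flip_angles",
]


class NoiseModel(BaseModel):
    """Additive per-image noise on each of S1 and S2."""

    model_config = {"frozen": True}

    sigma: float = Field(gt=0)
    independent: bool = True


def uni_statistic(s1, s2):
    """Signed-real UNI ratio ``S1 S2 / (S1^2 + S2^2)``, bounded in [-1/2, 1/2]."""
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    den = s1 * s1 + s2 * s2
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, s1 * s2 / np.where(den > 0, den, 1.0), 0.0)
    return out


def _uni_partials(s1, s2):
    den = (s1 * s1 + s2 * s2) ** 2
    d1 = s2 * (s2 * s2 - s1 * s1) / den
    d2 = s1 * (s1 * s1 - s2 * s2) / den
    return d1, d2


def propagate_uni_noise(s: SignalPair, nm: NoiseModel) -> float:
    """Delta-method standard deviation of the UNI statistic.

    Uses analytic partial derivatives of UNI with respect to the signed
    signals; raises when both signals vanish (UNI undefined there).
    """
    s1, s2 = float(s.S1), float(s.S2)
    if s1 == 0.0 and s2 == 0.0:
        raise ValueError("UNI undefined at S1 = S2 = 0")
    d1, d2 = _uni_partials(s1, s2)
    return float(nm.sigma * np.hypot(d1, d2))


@dataclass(frozen=True)
class CNRSurface:
    """CNR evaluated on a flip-angle grid, with its argmax."""

    alpha1_grid: np.ndarray  # degrees
    alpha2_grid: np.ndarray
    cnr: np.ndarray  # shape (len(alpha1_grid), len(alpha2_grid))
    argmax: Tuple[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cnr, index=self.alpha1_grid, columns=self.alpha2_grid)
        df.index.name = "alpha1_deg"
        df.columns.name = "alpha2_deg"
        return df


def _grid_argmax(cnr: np.ndarray, a1: np.ndarray, a2: np.ndarray) -> Tuple[int, int]:
    """Index of the maximum; ties broken toward the smaller alpha1 + alpha2."""
    best = cnr.max()
    ii, jj = np.nonzero(cnr == best)
    sums = a1[ii] + a2[jj]
    k = int(np.lexsort((a2[jj], a1[ii], sums))[0])
    return int(ii[k]), int(jj[k])


def cnr_surface(
    p: ProtocolConfig,
    gm: TissueParams,
    wm: TissueParams,
    nm: NoiseModel,
    alpha1_grid=None,
    alpha2_grid=None,
    statistic: str = "uni",
) -> CNRSurface:
    """GM-WM CNR over a grid of flip-angle pairs at nominal b1 = 1.

    ``statistic`` selects the contrast measure: ``"uni"`` (default) or
    ``"difference"`` (raw S1 contrast is not meaningful across two TIs, so
    the difference mode contrasts the per-tissue (S1 - S2) combination with
    plain noise propagation sqrt(2) sigma).
    """
    a1 = np.arange(1.0, 46.0) if alpha1_grid is None else np.asarray(alpha1_grid, float)
    a2 = np.arange(1.0, 46.0) if alpha2_grid is None else np.asarray(alpha2_grid, float)
    if a1.min() < 0 or a1.max() > 90 or a2.min() < 0 or a2.max() > 90:
        raise ValueError("flip-angle grids must lie within [0, 90] degrees")

    A1, A2 = np.meshgrid(a1, a2, indexing="ij")
    sg1, sg2 = signal_arrays(p, gm.T1, gm.M0, 1.0, alpha1=A1, alpha2=A2)
    sw1, sw2 = signal_arrays(p, wm.T1, wm.M0, 1.0, alpha1=A1, alpha2=A2)
    if statistic == "uni":
        ug = uni_statistic(sg1, sg2)
        uw = uni_statistic(sw1, sw2)
        with np.errstate(invalid="ignore", divide="ignore"):
            dg1, dg2 = _uni_partials(sg1, sg2)
            dw1, dw2 = _uni_partials(sw1, sw2)
            var = nm.sigma**2 * (dg1**2 + dg2**2 + dw1**2 + dw2**2)
            cnr = np.where(var > 0, np.abs(ug - uw) / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
        cnr = np.nan_to_num(cnr, nan=0.0, posinf=0.0)
    elif statistic == "difference":
        cnr = np.abs((sg1 - sg2) - (sw1 - sw2)) / (2.0 * nm.sigma)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    ii, jj = _grid_argmax(cnr, a1, a2)
    return CNRSurface(alpha1_grid=a1, alpha2_grid=a2, cnr=cnr, argmax=(a1[ii], a2[jj]))


def optimize_flip_angles(surface: CNRSurface) -> Tuple[float, float, float]:
    """Refined CNR-optimal flip-angle pair from a computed surface.

    Takes the global grid maximum (ties toward smaller alpha1 + alpha2) and
    refines each coordinate by the vertex of the parabola through the 3-point
    neighbourhood, clipped to one grid step.  Returns (alpha1*, alpha2*, CNR*).
    """
    cnr, a1, a2 = surface.cnr, surface.alpha1_grid, surface.alpha2_grid
    if cnr.size == 0:
        raise ValueError("empty surface")
    if np.all(cnr == 0):
        raise ValueError("no contrast: CNR surface is identically zero")
    ii, jj = _grid_argmax(cnr, a1, a2)

    def refine(grid, values, k):
        if 0 < k < len(grid) - 1:
            y0, y1, y2 = values[k - 1], values[k], values[k + 1]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                delta = 0.5 * (y0 - y2) / denom
                delta = float(np.clip(delta, -1.0, 1.0))
                step = grid[min(k + 1, len(grid) - 1)] - grid[k] if delta >= 0 else grid[k] - grid[k - 1]
                return float(grid[k] + delta * abs(step))
        return float(grid[k])

    a1_star = refine(a1, cnr[:, jj], ii)
    a2_star = refine(a2, cnr[ii, :], jj)
    # CNR at the refined point: bilinear estimate from the grid
    c_star = float(cnr[ii, jj])
    return a1_star, a2_star, c_star
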