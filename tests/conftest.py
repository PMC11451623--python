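"""Shared fixtures and independent oracles.

The brute-force oracle here iterates the inversion-recovery cycle event by
event for many consecutive cycles, starting from thermal equilibrium — a
deliberately naive reference for the closed-form fixed-point steady state
used by the package.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from t1epi.config import ProtocolConfig, TissueParams, default_protocol


@pytest.fixture(scope="session")
def protocol() -> ProtocolConfig:
    return default_protocol()


@pytest.fixture(scope="session")
def small_protocol() -> ProtocolConfig:
    """A reduced matrix for fast voxelwise work; same timing structure."""
    return default_protocol().model_copy(update={"N": (48, 48, 48)})


def brute_force_signals(p: ProtocolConfig, t: TissueParams, b1: float = 1.0,
                        n_cycles: int = 500):
    """(S1, S2) by naive event-by-event iteration from Mz = M0."""
    from t1epi.bloch import _pulse_times

    t1s, t2s = _pulse_times(p)
    c = p.center_index
    cos1 = math.cos(math.radians(p.alpha1) * b1)
    cos2 = math.cos(math.radians(p.alpha2) * b1)
    m = 1.0
    pre = {}
    for _ in range(n_cycles):
        m = -p.eps_inv * m
        t_prev = 0.0
        for blk, (times, cosa) in enumerate(((t1s, cos1), (t2s, cos2)), start=1):
            for k, tk in enumerate(times):
                e = math.exp(-(tk - t_prev) / t.T1)
                m = m * e + (1.0 - e)
                t_prev = tk
                if k == c:
                    pre[blk] = m
                m *= cosa
        e = math.exp(-(p.TR_IR - t_prev) / t.T1)
        m = m * e + (1.0 - e)
    s1 = t.M0 * pre[1] * math.sin(math.radians(p.alpha1) * b1)
    s2 = t.M0 * pre[2] * math.sin(math.radians(p.alpha2) * b1)
    return s1, s2


def brute_force_trajectory(p: ProtocolConfig, t: TissueParams, b1: float = 1.0,
                           n_cycles: int = 500):
    """Pre-pulse Mz samples of the final cycle of naive iteration."""
    from t1epi.bloch import _pulse_times

    t1s, t2s = _pulse_times(p)
    cos1 = math.cos(math.radians(p.alpha1) * b1)
    cos2 = math.cos(math.radians(p.alpha2) * b1)
    m = 1.0
    for cycle in range(n_cycles):
        m = -p.eps_inv * m
        t_prev = 0.0
        times, values = [], []
        for times_blk, cosa in ((t1s, cos1), (t2s, cos2)):
            for tk in times_blk:
                e = math.exp(-(tk - t_prev) / t.T1)
                m = m * e + (1.0 - e)
                t_prev = tk
                times.append(tk)
                values.append(m * t.M0)
                m *= cosa
        e = math.exp(-(p.TR_IR - t_prev) / t.T1)
        m = m * e + (1.0 - e)
    return np.asarray(times), np.asarray(values)
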