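"""Synthetic digital phantom and forward acquisition simulator.

Generates a brain-like concentric geometry — a white-matter core, a
grey-matter ribbon, and a CSF rim, optionally folded by a sinusoidal angular
perturbation — together with voxelwise T1/M0 maps, a smooth band-limited B0
field and a smooth B1 transmit template.  The forward simulator turns a
phantom and a protocol into the full eight-image polarity set: steady-state
signals per TI from the Bloch model, a read-polarity-odd multiplicative
ripple artifact (a synthetic stand-in for trajectory-imperfection "fuzzy
ripples"), the PE-polarity-dependent B0 distortion, and complex Gaussian
noise.  The artifact operators are exactly the ones the correction modules
invert, so cancellation and unwarping tests are closed-loop.

All outputs are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .bloch import signal_arrays
from .config import CSF_7T, GM_7T, WM_7T, ProtocolConfig, TissueParams
from .distortion import FieldMap, apply_distortion
from .combine import PolarityImage, PolarityImageSet
from .io import ImageVolume
from .lookup import B1Map

__all__ = [
    "Phantom",
    "RippleSpec",
    "generate_phantom",
    "generate_field_maps",
    "ripple_modulation",
    "simulate_acquisition",
]

LABEL_BACKGROUND, LABEL_CSF, LABEL_GM, LABEL_WM = 0, 1, 2, 3

DEFAULT_TISSUES: Dict[int, TissueParams] = {
    LABEL_CSF: CSF_7T,
    LABEL_GM: GM_7T,
    LABEL_WM: WM_7T,
}


@dataclass(frozen=True)
class Phantom:
    """Tissue labels plus voxelwise ground-truth parameter maps."""

    labels: np.ndarray  # 0 bg, 1 CSF, 2 GM, 3 WM
    T1: np.ndarray  # ms, 0 outside support
    M0: np.ndarray  # a.u., 0 outside support
    B0: FieldMap  # Hz
    B1: B1Map  # relative
    voxel_size_mm: float = 0.8

    @property
    def support(self) -> np.ndarray:
        return self.labels > 0

    def tissue_mask(self, label: int) -> np.ndarray:
        return self.labels == label


@dataclass(frozen=True)
class RippleSpec:
    """Low-spatial-frequency multiplicative ripple along the readout axis.

    ``amplitude`` is the modulation fraction of the local signal,
    ``cycles_per_fov`` its spatial frequency.  With ``odd_in_read_polarity``
    the modulation multiplies the signal by ``1 + r * m(x)`` so it inverts
    with read polarity r — the property dual-polarity averaging exploits.
    """

    amplitude: float = 0.1
    cycles_per_fov: float = 3.0
    odd_in_read_polarity: bool = True

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("ripple amplitude must be >= 0")


def _radial_coordinates(shape, fold_amplitude: float, fold_cycles: int):
    grids = np.meshgrid(*[np.linspace(-1.0, 1.0, s) for s in shape], indexing="ij")
    x, y, z = grids
    r = np.sqrt(x * x + y * y + z * z)
    if fold_amplitude > 0:
        theta = np.arctan2(y, x)
        phi = np.arctan2(z, np.hypot(x, y))
        r = r * (1.0 + fold_amplitude * np.sin(fold_cycles * theta) * np.cos(2 * phi))
    return r


def generate_phantom(
    seed: int,
    shape: Tuple[int, int, int] = (64, 64, 64),
    voxel_size_mm: float = 0.8,
    gm_thickness_frac: float = 0.18,
    csf_thickness_frac: float = 0.10,
    outer_radius: float = 0.85,
    fold_amplitude: float = 0.06,
    fold_cycles: int = 5,
    t1_variation: float = 0.0,
    b0_peak_hz: float = 20.0,
    b1_inhomogeneity: float = 0.15,
    tissues: Dict[int, TissueParams] | None = None,
) -> Phantom:
    """Deterministic concentric brain-like phantom.

    Radii are fractions of the half-field-of-view: the CSF rim occupies the
    outer ``csf_thickness_frac`` of ``outer_radius``, the GM ribbon the next
    ``gm_thickness_frac``, and WM the core.  ``t1_variation`` adds smooth
    multiplicative within-tissue variation of that fractional amplitude.
    """
    if any(s < 32 for s in shape):
        raise ValueError("phantom shape must be at least 32 per axis")
    rng = np.random.default_rng(seed)
    tissues = DEFAULT_TISSUES if tissues is None else tissues

    r = _radial_coordinates(shape, fold_amplitude, fold_cycles)
    r_csf_in = outer_radius * (1.0 - csf_thickness_frac)
    r_gm_in = r_csf_in - outer_radius * gm_thickness_frac
    labels = np.zeros(shape, dtype=np.int8)
    labels[r < outer_radius] = LABEL_CSF
    labels[r < r_csf_in] = LABEL_GM
    labels[r < r_gm_in] = LABEL_WM

    T1 = np.zeros(shape)
    M0 = np.zeros(shape)
    for lab, tp in tissues.items():
        m = labels == lab
        T1[m] = tp.T1
        M0[m] = tp.M0
    if t1_variation > 0:
        noise = gaussian_filter(rng.standard_normal(shape), max(shape) / 12)
        noise = noise / max(np.abs(noise).max(), 1e-12)
        T1 = T1 * (1.0 + t1_variation * noise)

    b0, b1 = generate_field_maps(
        int(rng.integers(0, 2**31 - 1)),
        shape,
        peak_hz=b0_peak_hz,
        b1_inhomogeneity=b1_inhomogeneity,
        support=labels > 0,
    )
    return Phantom(labels=labels, T1=T1, M0=M0, B0=b0, B1=b1,
                   voxel_size_mm=voxel_size_mm)


def generate_field_maps(
    seed: int,
    shape: Tuple[int, int, int],
    peak_hz: float = 20.0,
    b1_inhomogeneity: float = 0.15,
    smooth_frac: float = 0.15,
    support: np.ndarray | None = None,
) -> Tuple[FieldMap, B1Map]:
    """Smooth band-limited off-resonance and transmit-field templates.

    B0 is zero-mean over the support with max |B0| equal to ``peak_hz``;
    B1 is a low-order smooth field of mean 1 with peak deviation
    ``b1_inhomogeneity``.  ``smooth_frac`` sets the Gaussian correlation
    scale as a fraction of the grid size.
    """
    if peak_hz < 0:
        raise ValueError("peak_hz must be >= 0")
    rng = np.random.default_rng(seed)
    sup = np.ones(shape, bool) if support is None else support
    sigma = smooth_frac * max(shape)

    def smooth_field(scale):
        f = gaussian_filter(rng.standard_normal(shape), scale)
        return f

    # B0 stays smooth across the support edge (a hard cut would fake a shift
    # discontinuity no real susceptibility field has); zero-mean over support
    b0 = smooth_field(sigma)
    b0 = b0 - b0[sup].mean()
    peak = np.abs(b0).max()
    b0 = np.zeros(shape) if peak_hz == 0 or peak == 0 else b0 * (peak_hz / peak)

    # low-order polynomial bowl plus a gentle random component, centred on 1
    grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape], indexing="ij")
    bowl = sum(g * g for g in grids) / 3.0
    rand = smooth_field(2 * sigma)
    rand = rand / max(np.abs(rand).max(), 1e-12)
    b1 = 1.0 + b1_inhomogeneity * (0.7 * (0.5 - bowl) + 0.3 * rand)
    b1 = b1 - (b1[sup].mean() - 1.0)
    return FieldMap(b0), B1Map(np.clip(b1, 0.1, None))


def ripple_modulation(shape, spec: RippleSpec, read_axis: int = 0) -> np.ndarray:
    """The ripple's multiplicative modulation field m(x) (without polarity)."""
    n = shape[read_axis]
    x = np.arange(n) / n
    wave = spec.amplitude * np.sin(2 * np.pi * spec.cycles_per_fov * x)
    expand = [None] * len(shape)
    expand[read_axis] = slice(None)
    return np.broadcast_to(wave[tuple(expand)], shape)


def simulate_acquisition(
    phantom: Phantom,
    p: ProtocolConfig,
    ripple: RippleSpec | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    read_axis: int = 0,
    pe_axis: int = 1,
    interp: str = "linear",
) -> PolarityImageSet:
    """Forward-simulate the eight-image polarity set from a phantom.

    Per voxel and TI the signed steady-state signal comes from the Bloch
    model with the phantom's local T1, M0 and B1; each (read, phase)
    polarity combination is then modulated by the ripple (sign flipping with
    read polarity when the spec says so), distorted along the PE axis with
    the phantom B0 and the protocol's effective echo spacing, and corrupted
    with independent complex Gaussian noise of ``noise_sigma`` per channel.
    """
    sup = phantom.support
    t1 = np.where(sup, phantom.T1, 1000.0)  # placeholder outside support
    s1, s2 = signal_arrays(p, t1, phantom.M0, phantom.B1.data)
    s1 = np.where(sup, s1, 0.0)
    s2 = np.where(sup, s2, 0.0)

    mod = None
    if ripple is not None and ripple.amplitude > 0:
        mod = ripple_modulation(phantom.labels.shape, ripple, read_axis)

    rng = np.random.default_rng(seed)
    affine = np.diag([phantom.voxel_size_mm] * 3 + [1.0])
    images = []
    npe = phantom.labels.shape[pe_axis]
    distort = np.any(phantom.B0.data != 0)
    for r in (+1, -1):
        for d in (+1, -1):
            for ti, base in ((1, s1), (2, s2)):
                img = base.astype(complex)
                if mod is not None:
                    factor = r if ripple.odd_in_read_polarity else 1
                    img = img * (1.0 + factor * mod)
                vol = ImageVolume(img, affine, pe_axis=pe_axis)
                if distort:
                    vol = apply_distortion(vol, phantom.B0, p.esp_eff, d,
                                           npe, interp=interp)
                if noise_sigma > 0:
                    noise = noise_sigma * (
                        rng.standard_normal(img.shape)
                        + 1j * rng.standard_normal(img.shape)
                    )
                    vol = vol.with_data(vol.data + noise)
                images.append(
                    PolarityImage(volume=vol, read_polarity=r,
                                  phase_polarity=d, ti_index=ti)
                )
    return PolarityImageSet(images)
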