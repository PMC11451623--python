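"""Polarity combination, UNI reconstruction, and temporal SNR.

The acquisition repeats each two-TI volume four times, once per combination
of read polarity (direction of readout-gradient traversal) and phase-encode
polarity (direction of ky traversal).  Trajectory-imperfection artifacts
("fuzzy ripples") flip sign with read polarity and B0 distortions mirror
with phase-encode polarity, so a complex average over the four combinations
cancels the former, averages down noise, and — once distortions are matched
or removed — leaves an artifact-mitigated pair of TI images from which the
bias-cancelling UNI image is computed:

    UNI = Re(conj(S1) S2) / (|S1|^2 + |S2|^2)   in [-1/2, 1/2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Optional, Tuple

import numpy as np

from .io import ImageVolume

__all__ = [
    "PolarityImage",
    "PolarityImageSet",
    "uni_image",
    "combine_polarity_set",
    "tsnr_map",
]


@dataclass(frozen=True)
class PolarityImage:
    """A complex volume tagged with its read/phase polarity and TI index."""

    volume: ImageVolume
    read_polarity: int  # +1 or -1
    phase_polarity: int  # +1 or -1
    ti_index: int  # 1 or 2

    def __post_init__(self):
        if self.read_polarity not in (+1, -1) or self.phase_polarity not in (+1, -1):
            raise ValueError("polarities must be +1 or -1")
        if self.ti_index not in (1, 2):
            raise ValueError("ti_index must be 1 or 2")
        if not self.volume.is_complex:
            object.__setattr__(self, "volume",
                               self.volume.with_data(self.volume.data.astype(complex)))


_COMBOS = tuple((r, d) for r in (+1, -1) for d in (+1, -1))


class PolarityImageSet:
    """The eight images of one acquisition: 4 polarity combos x 2 TIs."""

    def __init__(self, images: Iterable[PolarityImage]):
        self._by_key: Dict[Tuple[int, int, int], PolarityImage] = {}
        for im in images:
            key = (im.read_polarity, im.phase_polarity, im.ti_index)
            if key in self._by_key:
                raise ValueError(f"duplicate polarity image {key}")
            self._by_key[key] = im
        expected = {(r, d, ti) for r, d in _COMBOS for ti in (1, 2)}
        missing = expected - set(self._by_key)
        if missing:
            raise ValueError(f"incomplete polarity set; missing {sorted(missing)}")
        shapes = {im.volume.shape for im in self._by_key.values()}
        if len(shapes) != 1:
            raise ValueError("polarity images are not on congruent grids")

    def get(self, r: int, d: int, ti: int) -> PolarityImage:
        return self._by_key[(r, d, ti)]

    def ti_images(self, ti: int):
        return [self._by_key[(r, d, ti)] for r, d in _COMBOS]

    @property
    def reference(self) -> ImageVolume:
        return self._by_key[(+1, +1, 1)].volume


def uni_image(s1: ImageVolume, s2: ImageVolume) -> ImageVolume:
    """Bias-cancelling UNI ratio of the two TI volumes, bounded in [-1/2, 1/2].

    Voxels with zero total power are set to 0 (they carry no signal).
    """
    if s1.shape != s2.shape:
        raise ValueError("TI volumes must share a grid")
    a = np.asarray(s1.data, dtype=complex)
    b = np.asarray(s2.data, dtype=complex)
    den = np.abs(a) ** 2 + np.abs(b) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        uni = np.where(den > 0, (np.conj(a) * b).real / np.where(den > 0, den, 1.0), 0.0)
    return s1.with_data(uni)


def _align_phase(data: np.ndarray, ref: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Remove the global phase offset of ``data`` relative to ``ref``.

    The offset is the phase of the masked inner product <ref, data>; complex
    averaging of images with misaligned global phases would destroy signal.
    """
    inner = np.vdot(ref[mask], data[mask])
    if inner == 0:
        return data
    return data * np.exp(-1j * np.angle(inner))


def combine_polarity_set(
    pset: PolarityImageSet,
    mode: str = "acquisition-space",
    field=None,
    esp_eff: Optional[float] = None,
) -> Tuple[ImageVolume, ImageVolume, ImageVolume]:
    """Complex-average the four polarity acquisitions per TI; compute UNI.

    ``acquisition-space`` (default) averages the images as acquired —
    appropriate when distortions are matched or negligible.  ``unwarp-first``
    removes the phase-encode-polarity-dependent B0 distortion of each image
    with the supplied field map (Hz) before averaging.  Each image's global
    phase is aligned to the first before the mean.  Returns
    ``(S1_combined, S2_combined, UNI)``.
    """
    if mode not in ("acquisition-space", "unwarp-first"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "unwarp-first" and field is None:
        raise ValueError("unwarp-first mode requires a field map")

    combined = {}
    for ti in (1, 2):
        images = pset.ti_images(ti)
        arrays = []
        for im in images:
            data = im.volume.data
            if mode == "unwarp-first":
                from .distortion import apply_distortion  # local: avoid cycle

                if esp_eff is None:
                    raise ValueError("unwarp-first mode requires esp_eff (ms)")
                npe = data.shape[im.volume.pe_axis]
                unwarped = apply_distortion(
                    im.volume, field, esp_eff, -im.phase_polarity, npe
                )
                data = unwarped.data
            arrays.append(np.asarray(data, dtype=complex))
        ref = arrays[0]
        mask = np.abs(ref) > 0
        if not mask.any():
            mask = np.ones(ref.shape, dtype=bool)
        aligned = [ref] + [_align_phase(a, ref, mask) for a in arrays[1:]]
        combined[ti] = images[0].volume.with_data(np.mean(aligned, axis=0))
    uni = uni_image(combined[1], combined[2])
    return combined[1], combined[2], uni


def tsnr_map(series: ImageVolume) -> ImageVolume:
    """Temporal SNR: voxelwise temporal mean over sample SD (ddof = 1).

    Needs at least three frames on the last axis; zero-variance voxels are
    reported as 0 rather than infinity.
    """
    data = np.asarray(series.data)
    if data.ndim != 4 or data.shape[-1] < 3:
        raise ValueError("tSNR needs a 4D series with >= 3 frames")
    if np.iscomplexobj(data):
        data = np.abs(data)
    mean = data.mean(axis=-1)
    sd = data.std(axis=-1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        tsnr = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), 0.0)
    return series.with_data(tsnr)
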