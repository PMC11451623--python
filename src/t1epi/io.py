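"""NIfTI input/output with phase-encode axis bookkeeping.

Volumes travel through the package as :class:`ImageVolume`: a real or complex
array of up to four dimensions, the NIfTI affine, and the index of the
phase-encode axis (y by default — the in-plane axis whose traversal
direction is reversed between the two phase-encode polarities).

Complex volumes are stored on disk as a real/imaginary pair of NIfTI files
(``<stem>_real.nii`` / ``<stem>_imag.nii``) with a small JSON sidecar noting
the convention; nonstandard complex NIfTI datatypes are deliberately avoided
for portability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "load_nifti", "save_nifti"]

DEFAULT_PE_AXIS = 1


@dataclass
class ImageVolume:
    """An image array with its voxel-to-world affine and PE-axis annotation."""

    data: np.ndarray
    affine: np.ndarray
    pe_axis: int = DEFAULT_PE_AXIS

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"expected 3D or 4D data, got {self.data.ndim}D")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.pe_axis not in (0, 1, 2):
            raise ValueError("phase-encode axis must be 0, 1 or 2")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.data)

    @property
    def shape(self):
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        return replace(self, data=np.asarray(data))


def _sidecar(path: Path) -> Path:
    return path.with_name(_stem(path) + "_complex.json")


def _stem(path: Path) -> str:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return name[: -len(suf)]
    return path.stem


def _part_path(path: Path, part: str) -> Path:
    name = path.name
    suffix = ".nii.gz" if name.endswith(".nii.gz") else ".nii"
    return path.with_name(_stem(path) + f"_{part}{suffix}")


def load_nifti(path: Path | str, pe_axis: int = DEFAULT_PE_AXIS) -> ImageVolume:
    """Load a NIfTI volume; reassemble a complex pair when one is found.

    ``path`` may be a plain file, the ``_real`` member of a real/imaginary
    pair, or the base name the pair was saved under.  Raises on missing
    files, non-NIfTI payloads and data with more than four dimensions.
    """
    path = Path(path)
    if not path.exists():
        base = path
        real, imag = _part_path(base, "real"), _part_path(base, "imag")
        if real.exists() and imag.exists():
            return _load_pair(real, imag, pe_axis)
        raise FileNotFoundError(path)
    if _sidecar(path).exists() or _stem(path).endswith("_real"):
        stem = _stem(path)
        if stem.endswith("_real"):
            base = path.with_name(stem[: -len("_real")] + ".nii")
        else:
            base = path
        real, imag = _part_path(base, "real"), _part_path(base, "imag")
        if real.exists() and imag.exists():
            return _load_pair(real, imag, pe_axis)
    img = _load_single(path)
    return ImageVolume(np.asarray(img.dataobj), img.affine, _header_pe(img, pe_axis))


def _header_pe(img, fallback: int) -> int:
    """PE axis from the NIfTI dim_info header field, if recorded."""
    try:
        _, phase, _ = img.header.get_dim_info()
    except AttributeError:
        return fallback
    return phase if phase is not None else fallback


def _load_single(path: Path):
    try:
        img = nib.load(str(path))
        if len(img.shape) > 4:
            raise ValueError(f"{path}: data has {len(img.shape)} dimensions (> 4)")
        np.asarray(img.dataobj)  # force read so truncation surfaces here
        return img
    except (nib.filebasedimages.ImageFileError, OSError, EOFError) as exc:
        raise ValueError(f"{path}: not a readable NIfTI file: {exc}") from exc


def _load_pair(real: Path, imag: Path, pe_axis: int) -> ImageVolume:
    re_img, im_img = _load_single(real), _load_single(imag)
    re, im = np.asarray(re_img.dataobj), np.asarray(im_img.dataobj)
    if re.shape != im.shape:
        raise ValueError("real/imaginary pair shapes differ")
    return ImageVolume(re + 1j * im, re_img.affine, _header_pe(re_img, pe_axis))


def save_nifti(vol: ImageVolume, path: Path | str) -> Path:
    """Write a volume; complex data become a ``_real``/``_imag`` pair.

    Returns the path written (the base path for complex pairs).  Non-finite
    data are rejected rather than silently stored.
    """
    path = Path(path)
    if not np.all(np.isfinite(vol.data)):
        raise ValueError("refusing to write non-finite data")
    path.parent.mkdir(parents=True, exist_ok=True)
    if vol.is_complex:
        for part, arr in (("real", vol.data.real), ("imag", vol.data.imag)):
            img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), vol.affine)
            img.header.set_dim_info(phase=vol.pe_axis)
            nib.save(img, str(_part_path(path, part)))
        _sidecar(path).write_text(
            json.dumps(
                {
                    "complex_pair": [_part_path(path, "real").name,
                                     _part_path(path, "imag").name],
                    "pe_axis": vol.pe_axis,
                }
            )
        )
        return path
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), vol.affine)
    img.header.set_dim_info(phase=vol.pe_axis)
    nib.save(img, str(path))
    return path
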