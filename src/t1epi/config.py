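"""Protocol and run configuration.

The sequence protocol is described by a :class:`ProtocolConfig`: the timing of
the inversion-recovery (IR) cycle, the two inversion times and their excitation
flip angles, the matrix/segmentation/undersampling geometry, and the effective
echo spacing that sets the EPI distortion magnitude.  Configurations can be
built in code or loaded from a plain-text ``key = value`` file (``#`` starts a
comment; keys match the field names below).
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

logger = logging.getLogger("t1epi")

__all__ = [
    "ProtocolConfig",
    "TissueParams",
    "RunConfig",
    "load_config",
    "parse_protocol_dict",
    "default_protocol",
    "default_config_path",
    "GM_7T",
    "WM_7T",
    "CSF_7T",
]


class ProtocolConfig(BaseModel):
    """Sequence protocol of the two-inversion segmented 3D-EPI acquisition.

    Times are in milliseconds, flip angles in degrees.  ``TI1``/``TI2`` run
    from the inversion pulse to the k-space-centre excitation of the first and
    second readout block.  ``seg`` is the number of shots (segments) per volume
    per inversion time; ``Rz`` the CAIPI undersampling factor along kz; ``pF``
    the phase partial-Fourier fraction; ``esp_eff`` the effective echo spacing
    along the phase-encode direction after segment interleaving.
    """

    model_config = {"frozen": True}

    TI1: float = 800.0
    TI2: float = 2700.0
    TR_IR: float = 3800.0
    TR_exc: Optional[float] = None  # derived from timing when None
    alpha1: float = 12.0
    alpha2: float = 4.0
    seg: int = 14
    Rz: int = 3
    pF: float = 0.75
    N: Tuple[int, int, int] = (232, 232, 186)
    n_combo: int = 4
    eps_inv: float = 1.0
    esp_eff: float = 0.10

    @field_validator("seg", "Rz")
    @classmethod
    def _positive_int(cls, v: int) -> int:
        if v < 1:
            raise ValueError("seg and Rz must be integers >= 1")
        return v

    @field_validator("pF")
    @classmethod
    def _pf_range(cls, v: float) -> float:
        if not 0.5 < v <= 1.0:
            raise ValueError(f"partial Fourier fraction must be in (0.5, 1], got {v}")
        return v

    @field_validator("eps_inv")
    @classmethod
    def _eps_range(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError(f"inversion efficiency must be in (0, 1], got {v}")
        return v

    @field_validator("alpha1", "alpha2")
    @classmethod
    def _alpha_range(cls, v: float) -> float:
        if not 0.0 <= v <= 90.0:
            raise ValueError(f"flip angles must be in [0, 90] degrees, got {v}")
        return v

    @field_validator("esp_eff")
    @classmethod
    def _esp_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("effective echo spacing must be > 0")
        return v

    @model_validator(mode="after")
    def _timing_order(self) -> "ProtocolConfig":
        if not 0.0 < self.TI1 < self.TI2 < self.TR_IR:
            raise ValueError(
                f"require 0 < TI1 < TI2 < TR_IR, got TI1={self.TI1}, "
                f"TI2={self.TI2}, TR_IR={self.TR_IR}"
            )
        if any(n < 1 for n in self.N):
            raise ValueError("matrix dimensions must be positive")
        if self.n_combo < 1:
            raise ValueError("n_combo must be >= 1")
        if self.TR_exc is not None and self.TR_exc <= 0:
            raise ValueError("TR_exc must be > 0")
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def n_exc(self) -> int:
        """Excitations per TI block: kz planes divided by CAIPI factor."""
        return math.ceil(self.N[2] / self.Rz)

    @property
    def center_index(self) -> int:
        """0-based index of the k-space-centre excitation within a block."""
        return self.n_exc // 2

    def resolved_tr_exc(self) -> float:
        """Excitation spacing within a block (ms).

        If not set explicitly, the largest spacing that packs both blocks
        around their TIs without overlap, with a 0.9 safety margin: the block
        of ``n_exc`` pulses is centred so that pulse ``center_index`` falls on
        the TI.
        """
        if self.TR_exc is not None:
            return self.TR_exc
        c = self.center_index
        tail = self.n_exc - 1 - c
        bounds = []
        if c > 0:
            bounds.append(self.TI1 / c)  # block 1 starts after the inversion
        if self.n_exc > 1:
            bounds.append((self.TI2 - self.TI1) / (self.n_exc - 1))  # no overlap
        if tail > 0:
            bounds.append((self.TR_IR - self.TI2) / tail)  # block 2 fits in cycle
        if not bounds:
            return 10.0
        return 0.9 * min(bounds)

    def displacement_per_hz(self) -> float:
        """PE-axis displacement per Hz of off-resonance, in voxels."""
        return self.esp_eff * 1e-3 * self.N[1]


class TissueParams(BaseModel):
    """Relaxation and density parameters of one tissue class."""

    model_config = {"frozen": True}

    name: str
    T1: float = Field(gt=0, description="longitudinal relaxation time (ms)")
    M0: float = Field(gt=0, description="equilibrium magnetization (a.u.)")


# 7 T simulation defaults; used by the phantom generator and design examples.
GM_7T = TissueParams(name="GM", T1=1800.0, M0=0.80)
WM_7T = TissueParams(name="WM", T1=1200.0, M0=0.70)
CSF_7T = TissueParams(name="CSF", T1=4000.0, M0=1.00)


class RunConfig(BaseModel):
    """A protocol plus reproducibility and output plumbing."""

    protocol: ProtocolConfig
    seed: int = 0
    out_dir: Path = Path(".")
    log_level: Literal["DEBUG", "INFO", "WARNING", "ERROR"] = "INFO"


_PROTOCOL_KEYS = set(ProtocolConfig.model_fields)
_RUN_KEYS = {"seed", "out_dir", "log_level"}
_REQUIRED_KEYS = ("TI1", "TI2", "TR_IR", "alpha1", "alpha2", "seg")


def _parse_value(key: str, raw: str):
    raw = raw.strip()
    if key == "N":
        parts = raw.replace("x", " ").replace(",", " ").split()
        if len(parts) != 3:
            raise ValueError(f"matrix size N needs three integers, got {raw!r}")
        return tuple(int(p) for p in parts)
    if key in ("seg", "Rz", "n_combo", "seed"):
        return int(raw)
    if key in ("out_dir", "log_level"):
        return raw
    return float(raw)


def parse_protocol_dict(pairs: dict) -> ProtocolConfig:
    """Validate a raw key/value mapping into a :class:`ProtocolConfig`."""
    unknown = set(pairs) - _PROTOCOL_KEYS
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    return ProtocolConfig(**pairs)


def load_config(path: Path | str) -> RunConfig:
    """Read a plain-text ``key = value`` configuration file.

    Raises on unknown keys and on any protocol invariant violation.  Fields
    absent from the file fall back to package defaults; each applied default
    is reported through the ``t1epi`` logger.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in _PROTOCOL_KEYS | _RUN_KEYS:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        pairs[key] = _parse_value(key, raw)
    if not pairs:
        raise ValueError(
            f"{path}: empty configuration; required keys include {_REQUIRED_KEYS}"
        )
    run_kwargs = {k: pairs.pop(k) for k in list(pairs) if k in _RUN_KEYS}
    protocol = parse_protocol_dict(pairs)
    for field in _PROTOCOL_KEYS - set(pairs):
        default = ProtocolConfig.model_fields[field].default
        logger.info("config %s: %s not given, default %r applied", path, field, default)
    return RunConfig(protocol=protocol, **run_kwargs)


def default_config_path() -> Path:
    """Path of the shipped default protocol file."""
    return Path(__file__).parent / "data" / "default_protocol.cfg"


def default_protocol() -> ProtocolConfig:
    """The shipped whole-brain 0.8 mm protocol."""
    return load_config(default_config_path()).protocol
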