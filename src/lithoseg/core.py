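"""Core domain containers shared across modules.

Coordinate conventions
----------------------
The world frame is in millimetres.  Voxel indices are 0-based and the value
of voxel ``(i, j, k)`` is located at its centre,
``origin_mm + (i, j, k) * spacing_mm``.  Hounsfield units (HU) throughout:
water = 0 HU, stones several hundred to >1000 HU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import ConfigurationError


class Method(str, Enum):
    """The four segmentation methods.

    ABS
        One absolute HU threshold (P1) shared by all stones.
    ABS_PV
        ABS plus surface partial-volume correction: a fraction P2 of the
        surface-voxel count is subtracted before the volume conversion.
    MED
        Per-stone adaptive threshold: P1 times the median HU of a rough
        low-threshold (20 HU) segmentation of that stone.
    MED_PV
        MED plus the surface partial-volume correction.
    """

    ABS = "abs"
    ABS_PV = "abs-pv"
    MED = "med"
    MED_PV = "med-pv"

    @property
    def uses_pv(self) -> bool:
        return self in (Method.ABS_PV, Method.MED_PV)

    @property
    def adaptive(self) -> bool:
        return self in (Method.MED, Method.MED_PV)


@dataclass
class CTVolume:
    """A 3D grid of HU values with physical voxel spacing."""

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise ConfigurationError("CTVolume requires a non-empty 3D grid")
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise ConfigurationError("spacing_mm must be 3 positive lengths")
        if self.origin_mm is None:
            self.origin_mm = np.zeros(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def world_to_index(self, point_mm: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of a world-frame point."""
        return (np.asarray(point_mm, dtype=float) - self.origin_mm) / self.spacing_mm

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        return self.origin_mm + np.asarray(index, dtype=float) * self.spacing_mm


@dataclass(frozen=True)
class Annotation:
    """Per-stone seed: a sphere guaranteed to contain the stone.

    Mirrors the circular markers a radiologist draws around each urolith,
    yielding a centre point and maximum radius.
    """

    stone_id: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if not self.radius_mm > 0:
            raise ConfigurationError(f"annotation {self.stone_id}: radius must be > 0")


@dataclass
class StoneMask:
    """Binary 3D segmentation aligned to a source CTVolume grid."""

    values: np.ndarray
    stone_id: str
    spacing_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.spacing_mm is not None:
            self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class MethodParams:
    """Method identifier plus its one or two free parameters.

    p1 is an absolute threshold in HU for ABS/ABS_PV, or a median fraction in
    (0, 1] for MED/MED_PV.  p2 is the surface factor in [0, 1), present
    exactly for the *_PV methods.
    """

    method: Method
    p1: float
    p2: float | None = None

    def __post_init__(self) -> None:
        method = Method(self.method)
        object.__setattr__(self, "method", method)
        if not self.p1 > 0:
            raise ConfigurationError("p1 must be > 0")
        if method.adaptive and self.p1 > 1:
            raise ConfigurationError("median-fraction p1 must lie in (0, 1]")
        if method.uses_pv:
            if self.p2 is None or not (0 <= self.p2 < 1):
                raise ConfigurationError(f"{method.value} requires p2 in [0, 1)")
        elif self.p2 is not None:
            raise ConfigurationError(f"{method.value} takes no p2")

    @property
    def pv_factor(self) -> float:
        return float(self.p2) if self.method.uses_pv else 0.0
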