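"""Core domain types shared by every pipeline stage.

Conventions fixed here and relied on everywhere downstream:

* volumes are indexed ``(z, y, x)``, 0-based, with ``z`` the coarsest
  (light-sheet) axis;
* voxel spacing is ``(dz, dy, dx)`` in micrometres and must be supplied
  explicitly — every headline measurement (volumes, distances, diameters,
  contact areas) is reported in physical units, never pixels;
* the three barcoding fluorophores tSapphire (S), Venus (V) and tdTomato (T)
  carry the bit values 1, 2 and 4, so a voxel's barcode code is an integer
  in 0–7 and the seven non-zero codes are the seven barcoded populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "DTYPE_ROLES",
    "VoxelGrid",
    "ChannelSet",
    "MetastasisRecord",
    "CODE_NAMES",
    "NAME_CODES",
    "code_name",
    "name_code",
    "parse_barcode_set",
    "format_barcode_set",
]

#: Valid interpretations of a grid's scalar values.
DTYPE_ROLES = frozenset(
    {"intensity", "binary", "label", "code", "distance_um", "thickness_um"}
)

#: code → short name for the 7 barcoded populations (S=1, V=2, T=4).
CODE_NAMES: dict[int, str] = {
    0: "none",
    1: "S",
    2: "V",
    3: "SV",
    4: "T",
    5: "ST",
    6: "VT",
    7: "SVT",
}
NAME_CODES: dict[str, int] = {name: code for code, name in CODE_NAMES.items()}


def code_name(code: int) -> str:
    """Short fluorophore-combination name for a barcode code (0–7)."""
    try:
        return CODE_NAMES[int(code)]
    except KeyError:
        raise ValueError(f"barcode code must be in 0–7, got {code!r}") from None


def name_code(name: str) -> int:
    """Inverse of :func:`code_name`."""
    try:
        return NAME_CODES[name]
    except KeyError:
        raise ValueError(f"unknown barcode name {name!r}") from None


def parse_barcode_set(text: str) -> frozenset[int]:
    """Parse a semicolon-separated set of BP names, e.g. ``"S;VT"`` → {1, 6}."""
    parts = [p.strip() for p in str(text).split(";") if p.strip()]
    codes = frozenset(name_code(p) for p in parts)
    if 0 in codes:
        raise ValueError("barcode set may not contain the background code")
    return codes


def format_barcode_set(codes: Iterable[int]) -> str:
    """Serialise a set of codes as sorted semicolon-separated names."""
    return ";".join(code_name(c) for c in sorted(set(int(c) for c in codes)))


@dataclass
class VoxelGrid:
    """A 3D scalar volume with physical voxel spacing.

    Parameters
    ----------
    data
        3D array indexed ``(z, y, x)``.
    spacing
        ``(dz, dy, dx)`` in μm; all components strictly positive and finite.
    dtype_role
        What the scalar values mean; one of :data:`DTYPE_ROLES`.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    dtype_role: str = "intensity"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D (z, y, x), got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)  # type: ignore[assignment]
        if len(self.spacing) != 3:
            raise ValueError("spacing must be (dz, dy, dx)")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing components must be positive and finite, got {self.spacing}")
        if self.dtype_role not in DTYPE_ROLES:
            raise ValueError(f"unknown dtype_role {self.dtype_role!r}")
        self._check_values()

    def _check_values(self) -> None:
        role = self.dtype_role
        if self.data.size == 0:
            return
        if role == "binary":
            bad = (self.data != 0) & (self.data != 1)
            if bad.any():
                raise ValueError("binary grid contains values outside {0, 1}")
        elif role == "code":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("code grid must be integer typed")
            if self.data.min() < 0 or self.data.max() > 7:
                raise ValueError("code grid values must lie in 0–7")
        elif role == "label":
            if not np.issubdtype(self.data.dtype, np.integer):
                raise ValueError("label grid must be integer typed")
            if self.data.min() < 0:
                raise ValueError("label grid values must be non-negative")
        elif role in ("distance_um", "thickness_um"):
            if self.data.min() < 0:
                raise ValueError(f"{role} grid must be non-negative")

    # -- convenience -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def with_data(self, data: np.ndarray, dtype_role: str | None = None) -> "VoxelGrid":
        """New grid sharing this grid's spacing."""
        return VoxelGrid(data, self.spacing, dtype_role or self.dtype_role)

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


@dataclass
class ChannelSet:
    """The four acquisition channels of one lobe: S, V, T and vessels.

    All grids must share shape and spacing.
    """

    sapphire: VoxelGrid
    venus: VoxelGrid
    tdtomato: VoxelGrid
    vessel: VoxelGrid

    def __post_init__(self) -> None:
        ref = self.sapphire
        for name in ("venus", "tdtomato", "vessel"):
            g = getattr(self, name)
            if not ref.same_geometry(g):
                raise ValueError(
                    f"channel {name!r} shape/spacing {g.shape}/{g.spacing} does not "
                    f"match sapphire {ref.shape}/{ref.spacing}"
                )

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.sapphire.spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.sapphire.shape

    def barcoding(self) -> tuple[VoxelGrid, VoxelGrid, VoxelGrid]:
        """The three fluorophore channels in bit order (S, V, T)."""
        return self.sapphire, self.venus, self.tdtomato


@dataclass
class MetastasisRecord:
    """One connected metastatic object and everything measured about it.

    ``volume_um3`` is exactly ``voxel_count × dz·dy·dx``; ``barcode_fractions``
    are per-code voxel fractions over the object and sum to 1;
    ``chromatic_class`` is ``"monochromatic"`` iff exactly one code was deemed
    present. Vessel-relation fields are filled by the vessels stage and may be
    ``nan`` until then.
    """

    object_id: int
    voxel_count: int
    volume_um3: float
    centroid: tuple[float, float, float]
    barcode_fractions: Mapping[int, float] = field(default_factory=dict)
    barcode_set: frozenset[int] = frozenset()
    chromatic_class: str = ""
    size_class: str = ""
    nearest_vessel_distance_um: float = float("nan")
    normalized_distance: float = float("nan")
    nearest_vessel_diameter_um: float = float("nan")
    contact_area_um2: float = float("nan")
    mouse_id: str = ""
    group: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.object_id <= 0:
            raise ValueError("object_id must be a positive label")
        if self.voxel_count < 0:
            raise ValueError("voxel_count must be non-negative")
        self.barcode_set = frozenset(int(c) for c in self.barcode_set)
        if any(c < 1 or c > 7 for c in self.barcode_set):
            raise ValueError("barcode_set codes must be in 1–7")

    def evolve(self, **changes) -> "MetastasisRecord":
        return replace(self, **changes)
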