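"""Readers and writers for volumes (multipage TIFF, Zarr) and record tables.

Volumes round-trip losslessly for integer data; floats are stored at native
precision. Voxel spacing is never defaulted: it is either given explicitly or
read from Zarr ``spacing`` attributes written by :func:`write_volume` — a TIFF
without an explicit spacing is an error, because every physical measurement
depends on it.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import zarr

from .core import MetastasisRecord, VoxelGrid, format_barcode_set, parse_barcode_set

__all__ = ["read_volume", "write_volume", "write_records", "read_records", "RECORD_COLUMNS"]

_TIFF_SUFFIXES = {".tif", ".tiff"}


def _is_zarr(path: Path) -> bool:
    return path.suffix == ".zarr" or (path.is_dir() and (path / "zarr.json").exists())


def read_volume(
    path: str | os.PathLike,
    spacing: Sequence[float] | None = None,
    dtype_role: str = "intensity",
) -> VoxelGrid:
    """Read a 3D volume from a multipage TIFF or a Zarr array.

    Parameters
    ----------
    path
        ``.tif``/``.tiff`` file or ``.zarr`` array directory.
    spacing
        ``(dz, dy, dx)`` in μm. Required for TIFF; for Zarr it may be omitted
        if the array carries a ``spacing`` attribute, and overrides it if given.
    dtype_role
        Role assigned to the returned grid.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    if _is_zarr(path):
        arr = zarr.open_array(str(path), mode="r")
        data = np.asarray(arr[:])
        if spacing is None:
            spacing = arr.attrs.get("spacing")
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        data = tifffile.imread(str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    if data.ndim != 3:
        raise ValueError(f"non-3D data: {path} has ndim={data.ndim}, expected 3")
    if spacing is None:
        raise ValueError(f"no voxel spacing given and none stored with {path}")
    return VoxelGrid(data, tuple(spacing), dtype_role)


def write_volume(grid: VoxelGrid, path: str | os.PathLike) -> Path:
    """Write a grid to multipage TIFF or Zarr (chosen by suffix).

    Parent directories are created. Zarr output stores the spacing as an
    array attribute so it round-trips without sidecar files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix == ".zarr":
        arr = zarr.create_array(
            store=str(path),
            shape=grid.data.shape,
            dtype=grid.data.dtype,
            overwrite=True,
        )
        arr[:] = grid.data
        arr.attrs["spacing"] = list(grid.spacing)
        arr.attrs["dtype_role"] = grid.dtype_role
    elif path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), grid.data, photometric="minisblack")
    else:
        raise ValueError(f"unsupported volume format: {path.suffix!r}")
    return path


#: Stable column order of the per-metastasis CSV.
RECORD_COLUMNS = [
    "object_id",
    "mouse_id",
    "group",
    "voxel_count",
    "volume_um3",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "barcode_set",
    "chromatic_class",
    "size_class",
    "nearest_vessel_distance_um",
    "normalized_distance",
    "nearest_vessel_diameter_um",
    "contact_area_um2",
    "corrected",
] + [f"fraction_{name}" for name in ("S", "V", "SV", "T", "ST", "VT", "SVT")]

_FRACTION_CODES = {f"fraction_{name}": code for code, name in
                   zip((1, 2, 3, 4, 5, 6, 7), ("S", "V", "SV", "T", "ST", "VT", "SVT"))}


def records_to_frame(records: Iterable[MetastasisRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "object_id": r.object_id,
            "mouse_id": r.mouse_id,
            "group": r.group,
            "voxel_count": r.voxel_count,
            "volume_um3": r.volume_um3,
            "centroid_z_um": r.centroid[0],
            "centroid_y_um": r.centroid[1],
            "centroid_x_um": r.centroid[2],
            "barcode_set": format_barcode_set(r.barcode_set),
            "chromatic_class": r.chromatic_class,
            "size_class": r.size_class,
            "nearest_vessel_distance_um": r.nearest_vessel_distance_um,
            "normalized_distance": r.normalized_distance,
            "nearest_vessel_diameter_um": r.nearest_vessel_diameter_um,
            "contact_area_um2": r.contact_area_um2,
            "corrected": r.corrected,
        }
        for col, code in _FRACTION_CODES.items():
            row[col] = float(r.barcode_fractions.get(code, 0.0))
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_records(records: Iterable[MetastasisRecord], path: str | os.PathLike) -> Path:
    """Write metastasis records as a CSV with the stable column schema."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records_to_frame(records).to_csv(path, index=False)
    return path


def read_records(path: str | os.PathLike) -> list[MetastasisRecord]:
    """Read a records CSV back into :class:`MetastasisRecord` objects."""
    df = pd.read_csv(path, keep_default_na=False, na_values=["nan", "NaN", ""])
    out: list[MetastasisRecord] = []
    for _, row in df.iterrows():
        fractions = {
            code: float(row[col]) for col, code in _FRACTION_CODES.items() if float(row[col]) > 0
        }
        barcode = row["barcode_set"]
        out.append(
            MetastasisRecord(
                object_id=int(row["object_id"]),
                voxel_count=int(row["voxel_count"]),
                volume_um3=float(row["volume_um3"]),
                centroid=(
                    float(row["centroid_z_um"]),
                    float(row["centroid_y_um"]),
                    float(row["centroid_x_um"]),
                ),
                barcode_fractions=fractions,
                barcode_set=parse_barcode_set(barcode) if isinstance(barcode, str) else frozenset(),
                chromatic_class=str(row["chromatic_class"]),
                size_class=str(row["size_class"]),
                nearest_vessel_distance_um=float(row["nearest_vessel_distance_um"]),
                normalized_distance=float(row["normalized_distance"]),
                nearest_vessel_diameter_um=float(row["nearest_vessel_diameter_um"]),
                contact_area_um2=float(row["contact_area_um2"]),
                mouse_id=str(row["mouse_id"]),
                group=str(row["group"]),
                corrected=bool(row["corrected"] in (True, "True", "true", 1, "1")),
            )
        )
    return out
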