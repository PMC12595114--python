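"""Bitwise barcode encoding and metastasis object extraction.

Each fluorophore mask carries one bit (S=1, V=2, T=4); summing the masked
bits gives every voxel a code in 0–7, the seven non-zero codes being the
seven barcoded populations (BPs). A metastasis is a connected component of
the union ("all metastasis") mask; objects smaller than ~one cell
(9000 μm³ by default) are discarded as noise, and each survivor is assigned
the set of codes occupying at least a small presence fraction of its voxels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import MetastasisRecord, VoxelGrid, parse_barcode_set

__all__ = [
    "BarcodeParams",
    "SIZE_BIN_PRESETS",
    "encode_barcodes",
    "encode_channels",
    "union_mask",
    "label_objects",
    "object_volumes",
    "build_records",
    "filter_small_objects",
    "assign_object_barcodes",
    "apply_corrections",
    "classify_size",
]


@dataclass
class BarcodeParams:
    """Object-extraction parameters.

    min_volume_um3 : exclusion threshold; objects with volume ≥ threshold are
        kept (default 9000 μm³ ≈ one cell).
    presence_fraction : minimum per-code voxel fraction for a code to count as
        present in an object (default 0.05); vetoes thin misassignment rims
        caused by overlap with neighbouring BPs.
    connectivity : 6 (faces), 18 (+edges) or 26 (+vertices) neighbourhood.
    """

    min_volume_um3: float = 9000.0
    presence_fraction: float = 0.05
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.min_volume_um3 < 0:
            raise ValueError("min_volume_um3 must be non-negative")
        if not 0.0 <= self.presence_fraction < 1.0:
            raise ValueError("presence_fraction must lie in [0, 1)")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be one of 6, 18, 26")


def _check_aligned(grids: Sequence[VoxelGrid]) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_geometry(g):
            raise ValueError(
                f"masks disagree in shape/spacing: {ref.shape}/{ref.spacing} vs {g.shape}/{g.spacing}"
            )


def encode_channels(masks: Sequence[VoxelGrid]) -> VoxelGrid:
    """Generalised bitwise encoder: channel i contributes bit ``2**i``.

    With k channels the non-zero codes are exactly the ``2**k − 1`` possible
    fluorophore combinations.
    """
    if not masks:
        raise ValueError("need at least one channel mask")
    _check_aligned(masks)
    code = np.zeros(masks[0].shape, dtype=np.int64)
    for i, m in enumerate(masks):
        code += (m.data != 0).astype(np.int64) << i
    role = "code" if len(masks) == 3 else "label"
    return VoxelGrid(code, masks[0].spacing, role)


def encode_barcodes(mask_s: VoxelGrid, mask_v: VoxelGrid, mask_t: VoxelGrid) -> VoxelGrid:
    """Combine the S, V, T masks into the 0–7 barcode code map (S=1, V=2, T=4)."""
    return encode_channels([mask_s, mask_v, mask_t])


def union_mask(mask_s: VoxelGrid, mask_v: VoxelGrid, mask_t: VoxelGrid) -> VoxelGrid:
    """The 'all metastasis' mask: 1 where any fluorophore channel is positive."""
    _check_aligned([mask_s, mask_v, mask_t])
    u = ((mask_s.data != 0) | (mask_v.data != 0) | (mask_t.data != 0)).astype(np.uint8)
    return VoxelGrid(u, mask_s.spacing, "binary")


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def label_objects(mask: VoxelGrid, connectivity: int = 26) -> tuple[VoxelGrid, int]:
    """Connected-component labelling of a binary mask; labels 1..N."""
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be one of 6, 18, 26")
    labels, n = ndimage.label(mask.data != 0, structure=_STRUCTURES[connectivity])
    return VoxelGrid(labels.astype(np.int32), mask.spacing, "label"), int(n)


def object_volumes(labels: VoxelGrid) -> dict[int, tuple[int, float, tuple[float, float, float]]]:
    """Per-object voxel count, physical volume and centroid.

    Returns ``{object_id: (voxel_count, volume_um3, (cz, cy, cx) μm)}`` with
    ``volume_um3 = voxel_count × dz·dy·dx`` exactly and centroids at the mean
    voxel-centre position (voxel centre i lies at ``i × spacing``).
    """
    data = labels.data
    n = int(data.max())
    if n == 0:
        return {}
    ids = np.arange(1, n + 1)
    counts = ndimage.sum_labels(np.ones_like(data, dtype=np.int64), data, ids)
    centroids = ndimage.center_of_mass(np.ones(data.shape), data, ids)
    vv = labels.voxel_volume_um3
    dz, dy, dx = labels.spacing
    out = {}
    for oid, cnt, (cz, cy, cx) in zip(ids, counts, centroids):
        cnt = int(cnt)
        if cnt == 0:
            continue
        out[int(oid)] = (cnt, cnt * vv, (cz * dz, cy * dy, cx * dx))
    return out


def build_records(labels: VoxelGrid, mouse_id: str = "", group: str = "") -> list[MetastasisRecord]:
    """Seed one record per labelled object with its geometry measurements."""
    return [
        MetastasisRecord(
            object_id=oid,
            voxel_count=cnt,
            volume_um3=vol,
            centroid=centroid,
            mouse_id=mouse_id,
            group=group,
        )
        for oid, (cnt, vol, centroid) in sorted(object_volumes(labels).items())
    ]


def filter_small_objects(
    records: Iterable[MetastasisRecord], min_volume_um3: float = 9000.0
) -> tuple[list[MetastasisRecord], list[int]]:
    """Drop objects below the single-cell volume threshold.

    The boundary is inclusive: objects *smaller than* the threshold are
    excluded, so a volume exactly at the threshold survives. Returns the
    surviving records (unmodified) and the removed object ids.
    """
    if min_volume_um3 < 0:
        raise ValueError("volume threshold must be non-negative")
    kept, removed = [], []
    for r in records:
        if r.volume_um3 >= min_volume_um3:
            kept.append(r)
        else:
            removed.append(r.object_id)
    return kept, removed


def assign_object_barcodes(
    records: Iterable[MetastasisRecord],
    labels: VoxelGrid,
    code_grid: VoxelGrid,
    presence_fraction: float = 0.05,
) -> list[MetastasisRecord]:
    """Assign per-object barcode fractions, barcode set and chromatic class.

    A code is deemed present when it occupies at least ``presence_fraction``
    of the object's voxels; if no code reaches the cutoff the single
    largest-fraction code is kept (ties to the smaller code). Monochromatic
    means exactly one code present.
    """
    if not labels.same_geometry(code_grid):
        raise ValueError("labels and code grid are not aligned")
    lab = labels.data
    codes = code_grid.data
    # joint histogram label × code
    n = int(lab.max())
    flat = lab.ravel().astype(np.int64) * 8 + codes.ravel().astype(np.int64)
    hist = np.bincount(flat[lab.ravel() != 0], minlength=(n + 1) * 8).reshape(n + 1, 8)
    out = []
    for r in records:
        counts = hist[r.object_id]
        zero_inside = counts[0]
        total = counts[1:].sum()
        if total == 0 or zero_inside > 0:
            raise ValueError(
                f"object {r.object_id} contains code-0 voxels: mask and code map disagree"
            )
        fractions = {c: counts[c] / total for c in range(1, 8) if counts[c] > 0}
        present = {c for c, f in fractions.items() if f >= presence_fraction}
        if not present:
            best = max(sorted(fractions), key=lambda c: fractions[c])
            present = {best}
        out.append(
            r.evolve(
                barcode_fractions=fractions,
                barcode_set=frozenset(present),
                chromatic_class="monochromatic" if len(present) == 1 else "polychromatic",
            )
        )
    return out


def apply_corrections(
    records: Iterable[MetastasisRecord],
    corrections: Mapping[int, frozenset[int]] | pd.DataFrame,
) -> list[MetastasisRecord]:
    """Apply manual barcode corrections by object id.

    ``corrections`` maps object_id → replacement barcode set, or is a
    DataFrame with columns ``object_id`` and ``new_barcode_set``
    (semicolon-separated BP names). Corrected records get a recomputed
    chromatic class and ``corrected=True``; unknown ids and empty
    replacement sets are errors.
    """
    if isinstance(corrections, pd.DataFrame):
        table = {
            int(row["object_id"]): parse_barcode_set(row["new_barcode_set"])
            for _, row in corrections.iterrows()
        }
    else:
        table = {int(k): frozenset(v) for k, v in corrections.items()}
    records = list(records)
    known = {r.object_id for r in records}
    unknown = set(table) - known
    if unknown:
        raise ValueError(f"corrections reference unknown object ids: {sorted(unknown)}")
    for oid, new_set in table.items():
        if not new_set:
            raise ValueError(f"empty replacement barcode set for object {oid}")
    out = []
    for r in records:
        if r.object_id in table:
            new_set = table[r.object_id]
            out.append(
                r.evolve(
                    barcode_set=new_set,
                    chromatic_class="monochromatic" if len(new_set) == 1 else "polychromatic",
                    corrected=True,
                )
            )
        else:
            out.append(r)
    return out


#: Size-class bin presets, half-open [lo, hi) in μm³. The four-bin preset caps
#: "large" at 5×10⁷ and adds "very_large" above it; the three-bin preset calls
#: everything above 10⁷ "large". Volumes below 10⁵ are "below_small".
SIZE_BIN_PRESETS: dict[str, list[tuple[str, float, float]]] = {
    "fig3": [
        ("small", 1e5, 1e6),
        ("medium", 1e6, 1e7),
        ("large", 1e7, 5e7),
        ("very_large", 5e7, float("inf")),
    ],
    "fig5": [
        ("small", 1e5, 1e6),
        ("medium", 1e6, 1e7),
        ("large", 1e7, float("inf")),
    ],
}


def classify_size(volume_um3: float, bin_preset: str = "fig3") -> str:
    """Size class of a metastasis volume under a bin preset (half-open bins)."""
    if bin_preset not in SIZE_BIN_PRESETS:
        raise ValueError(f"unknown bin preset {bin_preset!r}")
    if volume_um3 < 0:
        raise ValueError("volume must be non-negative")
    for name, lo, hi in SIZE_BIN_PRESETS[bin_preset]:
        if lo <= volume_um3 < hi:
            return name
    return "below_small"
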