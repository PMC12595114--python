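"""Cohort-level summaries and tests.

The sampling unit for inference is the mouse: object-level metrics are first
reduced to a per-mouse median (separately for monochromatic and polychromatic
metastases), and t-tests then compare those per-mouse values — paired when
contrasting chromatic classes within the same animals, independent when
contrasting the IV and MFP delivery routes. Objects are never pooled across
mice for a test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import MetastasisRecord, VoxelGrid, code_name

__all__ = [
    "BiomassSummary",
    "TTestResult",
    "biomass_fractions",
    "shannon_diversity",
    "count_fractions",
    "mono_poly_summary",
    "per_mouse_median",
    "paired_t_test",
    "independent_t_test",
]


@dataclass
class BiomassSummary:
    """Per-BP biomass fractions (codes 1–7) and the number of BPs detected."""

    fractions: dict[int, float]
    n_bps_detected: int
    total_biomass_um3: float

    def as_named(self) -> dict[str, float]:
        return {code_name(c): f for c, f in sorted(self.fractions.items())}


def biomass_fractions(code_grid: VoxelGrid, labels: VoxelGrid) -> BiomassSummary:
    """Biomass contribution of each BP within the surviving (labelled) objects.

    Biomass of a code = its voxel count inside labelled objects × voxel
    volume; fractions are normalised over codes 1–7. With no biomass at all
    the summary is all-zero.
    """
    if not code_grid.same_geometry(labels):
        raise ValueError("code grid and labels are not aligned")
    inside = labels.data != 0
    counts = np.bincount(code_grid.data[inside].ravel(), minlength=8)[1:8]
    vv = code_grid.voxel_volume_um3
    total = counts.sum()
    if total == 0:
        return BiomassSummary({c: 0.0 for c in range(1, 8)}, 0, 0.0)
    fractions = {c: counts[c - 1] / total for c in range(1, 8)}
    return BiomassSummary(fractions, int((counts > 0).sum()), float(total * vv))


def shannon_diversity(fractions: Sequence[float] | Mapping[int, float], base: float | None = None) -> float:
    """Shannon diversity H = −Σ pᵢ ln pᵢ over BP abundance fractions.

    Jointly captures richness and evenness; 0·ln 0 ≡ 0. Reported in nats by
    default; pass ``base`` (e.g. 2) for other units. Fractions must sum to 1
    within 1e−9.
    """
    p = np.asarray(list(fractions.values()) if isinstance(fractions, Mapping) else fractions, dtype=float)
    if (p < 0).any():
        raise ValueError("fractions must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {p.sum()!r})")
    nz = p[p > 0]
    h = float(-(nz * np.log(nz)).sum())
    if base is not None:
        h /= math.log(base)
    return h


def count_fractions(records: Iterable[MetastasisRecord]) -> dict[int, float]:
    """Per-BP fractions by metastasis count (monochromatic objects only carry
    one code; polychromatic objects contribute to each code they contain,
    weighted equally)."""
    weights: dict[int, float] = {c: 0.0 for c in range(1, 8)}
    total = 0.0
    for r in records:
        if not r.barcode_set:
            continue
        w = 1.0 / len(r.barcode_set)
        for c in r.barcode_set:
            weights[c] += w
        total += 1.0
    if total == 0:
        return weights
    return {c: w / total for c, w in weights.items()}


def mono_poly_summary(
    records: Iterable[MetastasisRecord],
    lung_volumes_um3: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Per-mouse monochromatic/polychromatic counts, proportions and biomass.

    Returns one row per mouse with counts, proportions, summed volumes and —
    when a per-mouse lung volume (μm³) is supplied — the percentage of lung
    volume occupied by each chromatic class.
    """
    rows: dict[str, dict] = {}
    for r in records:
        row = rows.setdefault(
            r.mouse_id,
            {"mouse_id": r.mouse_id, "group": r.group,
             "n_mono": 0, "n_poly": 0, "volume_mono_um3": 0.0, "volume_poly_um3": 0.0},
        )
        if r.chromatic_class == "monochromatic":
            row["n_mono"] += 1
            row["volume_mono_um3"] += r.volume_um3
        elif r.chromatic_class == "polychromatic":
            row["n_poly"] += 1
            row["volume_poly_um3"] += r.volume_um3
        else:
            raise ValueError(f"record {r.object_id} has no chromatic class")
    out = []
    for mouse_id, row in sorted(rows.items()):
        n = row["n_mono"] + row["n_poly"]
        row["proportion_mono"] = row["n_mono"] / n if n else float("nan")
        row["proportion_poly"] = row["n_poly"] / n if n else float("nan")
        if lung_volumes_um3 is not None:
            if mouse_id not in lung_volumes_um3:
                raise ValueError(f"no lung volume supplied for mouse {mouse_id!r}")
            lv = float(lung_volumes_um3[mouse_id])
            row["biomass_pct_mono"] = row["volume_mono_um3"] / lv * 100.0
            row["biomass_pct_poly"] = row["volume_poly_um3"] / lv * 100.0
        out.append(row)
    return pd.DataFrame(out)


def per_mouse_median(
    records: Iterable[MetastasisRecord], metric: str, by_class: bool = True
) -> pd.DataFrame:
    """Median of an object metric per (mouse, chromatic class).

    Even-count medians are the mean of the two central values; an empty
    (mouse, class) group yields no row rather than a zero — some animals
    genuinely lack, say, very large polychromatic metastases.
    """
    valid = {"normalized_distance", "nearest_vessel_distance_um",
             "nearest_vessel_diameter_um", "contact_area_um2", "volume_um3"}
    if metric not in valid:
        raise ValueError(f"metric must be one of {sorted(valid)}")
    rows = [
        {"mouse_id": r.mouse_id, "group": r.group,
         "chromatic_class": r.chromatic_class if by_class else "all",
         "value": getattr(r, metric)}
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["mouse_id", "group", "chromatic_class", "metric", "value"])
    med = (
        df.groupby(["mouse_id", "group", "chromatic_class"])["value"]
        .median()
        .reset_index()
    )
    med.insert(3, "metric", metric)
    return med


@dataclass
class TTestResult:
    """Two-sided t-test outcome; ``degenerate`` flags a zero-variance input
    for which the p-value is undefined."""

    t: float
    p: float
    n: int
    n2: int | None = None
    degenerate: bool = False


def paired_t_test(x: Sequence[float], y: Sequence[float]) -> TTestResult:
    """Classical two-sided paired t-test on per-mouse value pairs.

    t = d̄ / (s_d / √n) on the differences d = x − y, with n − 1 degrees of
    freedom. Zero-variance differences make the statistic undefined and are
    flagged rather than silently propagated.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        return TTestResult(t=0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean()),
                           p=float("nan"), n=n, degenerate=True)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TTestResult(t=float(t), p=float(p), n=n)


def independent_t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sided two-sample t-test (pooled-variance Student by default,
    Welch with ``equal_var=False``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("independent t-test needs at least 2 values per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        same = x.mean() == y.mean()
        return TTestResult(t=0.0 if same else math.copysign(math.inf, x.mean() - y.mean()),
                           p=1.0 if same else float("nan"),
                           n=x.size, n2=y.size, degenerate=True)
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(t), p=float(p), n=x.size, n2=y.size)
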