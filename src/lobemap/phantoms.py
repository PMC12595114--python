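"""Synthetic phantoms with analytic ground truth.

A phantom emulates the structure the pipeline assumes in real lobes: tubular
vessels of known radius, ellipsoidal barcoded metastases placed at controlled
edge-to-edge distances from the vasculature, a slowly varying additive
background, and Gaussian noise. Ground truth (volumes, barcode sets,
edge-to-edge distances, nearest-vessel diameters, contact flags) is computed
from the continuous geometry, never from the voxelised render, so it stays
independent of rasterisation choices.

Voxelisation rule: a voxel belongs to a shape iff its centre (index × spacing)
lies inside the continuous shape — consistent with the voxel-centre distance
semantics used by the measurement stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import ChannelSet, VoxelGrid, format_barcode_set

__all__ = [
    "Vessel",
    "Metastasis",
    "PhantomSpec",
    "generate_phantom",
    "generate_ground_truth",
    "preset_cohort",
    "COHORT_GROUPS",
]


@dataclass
class Vessel:
    """A straight tube: centreline segment (μm, (z,y,x)) and radius (μm)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("vessel radius must be positive")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


@dataclass
class Metastasis:
    """An axis-aligned ellipsoid with barcode content.

    ``code_fractions`` maps BP codes (1–7) to target voxel fractions summing
    to 1; the render partitions the ellipsoid into contiguous slabs matching
    the fractions to ±1 voxel.
    """

    centre_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    code_fractions: dict[int, float]

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if not self.code_fractions:
            raise ValueError("a metastasis needs at least one barcode code")
        if any(c < 1 or c > 7 for c in self.code_fractions):
            raise ValueError("codes must be in 1–7")
        s = sum(self.code_fractions.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"code fractions must sum to 1, got {s}")

    @property
    def volume_um3(self) -> float:
        a, b, c = self.semi_axes_um
        return 4.0 / 3.0 * math.pi * a * b * c

    @property
    def barcode_set(self) -> frozenset[int]:
        return frozenset(self.code_fractions)

    @property
    def max_semi_axis(self) -> float:
        return max(self.semi_axes_um)


@dataclass
class PhantomSpec:
    """Full generative description of one synthetic volume.

    Channel order for the per-channel parameters is (S, V, T, vessel).
    ``background_offset`` is a constant per channel; ``background_slope``
    scales a linear ramp rising along +y and +x; ``noise_sigma`` is the
    per-channel Gaussian σ. The seed fully determines the rendered output.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    vessels: list[Vessel] = field(default_factory=list)
    metastases: list[Metastasis] = field(default_factory=list)
    intensity: tuple[float, float, float, float] = (200.0, 200.0, 200.0, 200.0)
    background_offset: tuple[float, float, float, float] = (15.0, 15.0, 15.0, 15.0)
    background_slope: tuple[float, float, float, float] = (10.0, 10.0, 10.0, 10.0)
    noise_sigma: tuple[float, float, float, float] = (5.0, 5.0, 5.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError("shape must be three positive extents")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self._validate_geometry()

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical position of the last voxel centre per axis."""
        return tuple((n - 1) * s for n, s in zip(self.shape, self.spacing))

    def _validate_geometry(self) -> None:
        ext = self.extent_um
        for i, m in enumerate(self.metastases):
            for ax in range(3):
                if (m.centre_um[ax] - m.semi_axes_um[ax] < 0
                        or m.centre_um[ax] + m.semi_axes_um[ax] > ext[ax]):
                    raise ValueError(f"metastasis {i} extends outside the volume bounds")
        # pairwise disjointness via bounding spheres (conservative)
        for i in range(len(self.metastases)):
            for j in range(i + 1, len(self.metastases)):
                a, b = self.metastases[i], self.metastases[j]
                d = math.dist(a.centre_um, b.centre_um)
                if d <= a.max_semi_axis + b.max_semi_axis:
                    raise ValueError(f"metastases {i} and {j} overlap")


# ---------------------------------------------------------------------------
# continuous geometry


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    return float(np.linalg.norm(p - (a + t * ab)))


def _ellipsoid_segment_surface_distance(met: Metastasis, vessel: Vessel) -> float:
    """Signed distance from the ellipsoid surface to the vessel surface.

    Exact closed form for spheres (centre-to-segment distance minus both
    radii); for genuine ellipsoids the distance from the ellipsoid surface to
    the vessel axis is minimised numerically over the surface (the ellipsoids
    used here are near-spherical, so the minimiser is well behaved).
    """
    c = np.asarray(met.centre_um, dtype=float)
    a0 = np.asarray(vessel.p0, dtype=float)
    a1 = np.asarray(vessel.p1, dtype=float)
    axis_dist = _point_segment_distance(c, a0, a1)
    semis = np.asarray(met.semi_axes_um, dtype=float)
    if np.allclose(semis, semis[0]):
        return axis_dist - vessel.radius_um - float(semis[0])

    def surface_point(angles: np.ndarray) -> np.ndarray:
        theta, phi = angles
        u = np.array(
            [math.cos(phi), math.sin(phi) * math.cos(theta), math.sin(phi) * math.sin(theta)]
        )
        return c + semis * u

    def objective(angles: np.ndarray) -> float:
        return _point_segment_distance(surface_point(angles), a0, a1)

    # initialise pointing from the centre toward the nearest axis point
    ab = a1 - a0
    denom = float(ab @ ab)
    t = 0.0 if denom == 0 else float(np.clip((c - a0) @ ab / denom, 0.0, 1.0))
    d = (a0 + t * ab) - c
    n = np.linalg.norm(d)
    d = d / n if n > 0 else np.array([0.0, 0.0, 1.0])
    phi0 = math.acos(np.clip(d[0], -1, 1))
    theta0 = math.atan2(d[2], d[1])
    best = math.inf
    for dtheta in (0.0, 0.5, -0.5):
        res = minimize(
            objective, np.array([theta0 + dtheta, phi0]), method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 500},
        )
        best = min(best, float(res.fun))
    return best - vessel.radius_um


def generate_ground_truth(spec: PhantomSpec) -> pd.DataFrame:
    """Analytic ground-truth table for a phantom spec (no rendering).

    Edge-to-edge distances are clamped at 0; ``contact`` flags a raw analytic
    distance ≤ 0. Nearest-vessel diameter is that of the vessel minimising
    the edge distance.
    """
    rows = []
    for i, m in enumerate(spec.metastases, start=1):
        if spec.vessels:
            dists = [_ellipsoid_segment_surface_distance(m, v) for v in spec.vessels]
            k = int(np.argmin(dists))
            raw = float(dists[k])
            diameter = spec.vessels[k].diameter_um
        else:
            raw, diameter = float("inf"), float("nan")
        volume = m.volume_um3
        rows.append(
            {
                "met_id": i,
                "centre_z_um": m.centre_um[0],
                "centre_y_um": m.centre_um[1],
                "centre_x_um": m.centre_um[2],
                "semi_z_um": m.semi_axes_um[0],
                "semi_y_um": m.semi_axes_um[1],
                "semi_x_um": m.semi_axes_um[2],
                "volume_um3": volume,
                "equivalent_radius_um": (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0),
                "barcode_set": format_barcode_set(m.barcode_set),
                "chromatic_class": "monochromatic" if len(m.barcode_set) == 1 else "polychromatic",
                "edge_distance_um": max(raw, 0.0),
                "raw_edge_distance_um": raw,
                "nearest_vessel_diameter_um": diameter,
                "contact": raw <= 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering


def _voxel_axes(spec: PhantomSpec):
    return [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]


def _render_vessel_mask(spec: PhantomSpec) -> np.ndarray:
    zz, yy, xx = np.meshgrid(*_voxel_axes(spec), indexing="ij", sparse=True)
    mask = np.zeros(spec.shape, dtype=bool)
    for v in spec.vessels:
        a = np.asarray(v.p0, dtype=float)
        b = np.asarray(v.p1, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        pz, py, px = zz - a[0], yy - a[1], xx - a[2]
        if denom == 0:
            d2 = pz**2 + py**2 + px**2
        else:
            t = np.clip((pz * ab[0] + py * ab[1] + px * ab[2]) / denom, 0.0, 1.0)
            d2 = (pz - t * ab[0]) ** 2 + (py - t * ab[1]) ** 2 + (px - t * ab[2]) ** 2
        mask |= d2 <= v.radius_um**2
    return mask


def _render_code_map(spec: PhantomSpec) -> np.ndarray:
    """Voxel code map: each ellipsoid partitioned into contiguous x-slabs
    matching its code fractions to ±1 voxel."""
    code = np.zeros(spec.shape, dtype=np.int8)
    axes = _voxel_axes(spec)
    for m in spec.metastases:
        lo = [
            int(np.searchsorted(axes[ax], m.centre_um[ax] - m.semi_axes_um[ax] - 1e-9))
            for ax in range(3)
        ]
        hi = [
            int(np.searchsorted(axes[ax], m.centre_um[ax] + m.semi_axes_um[ax] + 1e-9))
            for ax in range(3)
        ]
        sub = [axes[ax][lo[ax]:hi[ax]] for ax in range(3)]
        zz, yy, xx = np.meshgrid(*sub, indexing="ij", sparse=False)
        inside = (
            ((zz - m.centre_um[0]) / m.semi_axes_um[0]) ** 2
            + ((yy - m.centre_um[1]) / m.semi_axes_um[1]) ** 2
            + ((xx - m.centre_um[2]) / m.semi_axes_um[2]) ** 2
        ) <= 1.0
        iz, iy, ix = np.nonzero(inside)
        if iz.size == 0:
            continue
        order = np.lexsort((iz, iy, ix))  # contiguous slabs along x
        n = iz.size
        codes = sorted(m.code_fractions)
        bounds = np.round(np.cumsum([m.code_fractions[c] for c in codes]) * n).astype(int)
        start = 0
        for c, stop in zip(codes, bounds):
            sel = order[start:stop]
            code[iz[sel] + lo[0], iy[sel] + lo[1], ix[sel] + lo[2]] = c
            start = stop
    return code


def generate_phantom(spec: PhantomSpec) -> tuple[ChannelSet, pd.DataFrame]:
    """Render a phantom spec into the four channels and return ground truth.

    The same spec and seed give bit-identical volumes; ground truth comes
    from :func:`generate_ground_truth` and never inspects the render.
    """
    rng = np.random.default_rng(spec.seed)
    code = _render_code_map(spec)
    vessel_mask = _render_vessel_mask(spec)
    ny, nx = spec.shape[1], spec.shape[2]
    ramp_y = (np.arange(ny) / max(ny - 1, 1))[None, :, None]
    ramp_x = (np.arange(nx) / max(nx - 1, 1))[None, None, :]
    ramp = (ramp_y + ramp_x) / 2.0

    grids = []
    fg_masks = [(code & 1) > 0, (code & 2) > 0, (code & 4) > 0, vessel_mask]
    for ch in range(4):
        img = np.zeros(spec.shape, dtype=np.float32)
        img += spec.background_offset[ch] + spec.background_slope[ch] * ramp
        img[fg_masks[ch]] += spec.intensity[ch]
        img += rng.normal(0.0, spec.noise_sigma[ch], size=spec.shape)
        grids.append(VoxelGrid(img.astype(np.float32), spec.spacing, "intensity"))

    channels = ChannelSet(sapphire=grids[0], venus=grids[1], tdtomato=grids[2], vessel=grids[3])
    return channels, generate_ground_truth(spec)


# ---------------------------------------------------------------------------
# (de)serialisation


def spec_to_dict(spec: PhantomSpec) -> dict:
    """Plain-dict form of a spec, suitable for JSON/YAML."""
    return {
        "shape": list(spec.shape),
        "spacing": list(spec.spacing),
        "vessels": [
            {"p0": list(v.p0), "p1": list(v.p1), "radius_um": v.radius_um}
            for v in spec.vessels
        ],
        "metastases": [
            {
                "centre_um": list(m.centre_um),
                "semi_axes_um": list(m.semi_axes_um),
                "code_fractions": {str(c): f for c, f in m.code_fractions.items()},
            }
            for m in spec.metastases
        ],
        "intensity": list(spec.intensity),
        "background_offset": list(spec.background_offset),
        "background_slope": list(spec.background_slope),
        "noise_sigma": list(spec.noise_sigma),
        "seed": spec.seed,
    }


def spec_from_dict(d: dict) -> PhantomSpec:
    """Inverse of :func:`spec_to_dict`."""
    return PhantomSpec(
        shape=tuple(int(v) for v in d["shape"]),
        spacing=tuple(float(v) for v in d["spacing"]),
        vessels=[
            Vessel(p0=tuple(v["p0"]), p1=tuple(v["p1"]), radius_um=float(v["radius_um"]))
            for v in d.get("vessels", [])
        ],
        metastases=[
            Metastasis(
                centre_um=tuple(m["centre_um"]),
                semi_axes_um=tuple(m["semi_axes_um"]),
                code_fractions={int(c): float(f) for c, f in m["code_fractions"].items()},
            )
            for m in d.get("metastases", [])
        ],
        intensity=tuple(d.get("intensity", (200.0,) * 4)),
        background_offset=tuple(d.get("background_offset", (15.0,) * 4)),
        background_slope=tuple(d.get("background_slope", (10.0,) * 4)),
        noise_sigma=tuple(d.get("noise_sigma", (5.0,) * 4)),
        seed=int(d.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# cohort presets

COHORT_GROUPS = ("IV", "MFP")

_COHORT_SHAPE = (64, 128, 128)
_COHORT_SPACING = (2.9, 1.22, 1.22)


def _place_metastases(
    rng: np.random.Generator,
    spec_shape,
    spacing,
    vessels: list[Vessel],
    requests: list[dict],
) -> list[Metastasis]:
    """Place ellipsoids around vessels at requested edge gaps (μm).

    Each request carries ``radius_um``, ``gap_um`` (negative for deliberate
    vessel contact), ``codes`` and optional ``aspect`` (semi-axis multipliers).
    Placement is rejection-sampled with a seeded generator; if a spot cannot
    be found near a vessel the object falls back to any in-bounds free spot
    (ground truth is recomputed from the final geometry either way).
    """
    ext = tuple((n - 1) * s for n, s in zip(spec_shape, spacing))
    placed: list[Metastasis] = []

    def edge_gap_to(centre, support, vessel: Vessel) -> float:
        a = np.asarray(vessel.p0)
        b = np.asarray(vessel.p1)
        return _point_segment_distance(np.asarray(centre), a, b) - vessel.radius_um - support

    def fits(centre, semis) -> bool:
        for ax in range(3):
            if centre[ax] - semis[ax] < 1.5 * spacing[ax] or centre[ax] + semis[ax] > ext[ax] - 1.5 * spacing[ax]:
                return False
        for other in placed:
            if math.dist(centre, other.centre_um) <= max(semis) + other.max_semi_axis + 8.0:
                return False
        return True

    def unambiguous(centre, support, nearest_gap) -> bool:
        # keep the nearest vessel well separated from the runner-up so the
        # recovered nearest-vessel identity (hence diameter) is unambiguous
        gaps = sorted(edge_gap_to(centre, support, v) for v in vessels)
        return len(gaps) < 2 or gaps[1] >= max(nearest_gap, 0.0) + 6.0

    # large objects are hardest to fit: place them first
    for req in sorted(requests, key=lambda q: -q["radius_um"]):
        r = req["radius_um"]
        aspect = req.get("aspect", (1.0, 1.0, 1.0))
        semis = tuple(r * a for a in aspect)
        support = max(semis)  # conservative reach toward the vessel
        target = None
        for attempt in range(4000):
            v = vessels[int(rng.integers(len(vessels)))]
            z = float(rng.uniform(support + 5.0, ext[0] - support - 5.0))
            theta = float(rng.uniform(0.0, 2.0 * math.pi))
            offset = v.radius_um + req["gap_um"] + support
            cy = v.p0[1] + offset * math.cos(theta)
            cx = v.p0[2] + offset * math.sin(theta)
            centre = (z, cy, cx)
            if fits(centre, semis) and unambiguous(centre, support, req["gap_um"]):
                target = centre
                break
        if target is None:  # crowded: free placement, truth follows geometry
            for attempt in range(8000):
                centre = tuple(
                    float(rng.uniform(semis[ax] + 2 * spacing[ax], ext[ax] - semis[ax] - 2 * spacing[ax]))
                    for ax in range(3)
                )
                if fits(centre, semis) and unambiguous(
                    centre, support, min(edge_gap_to(centre, support, v) for v in vessels)
                ):
                    target = centre
                    break
        if target is None:
            # last resort: drop the ambiguity constraint (geometry stays valid;
            # ground truth always follows the final placement)
            for attempt in range(8000):
                centre = tuple(
                    float(rng.uniform(semis[ax] + 2 * spacing[ax], ext[ax] - semis[ax] - 2 * spacing[ax]))
                    for ax in range(3)
                )
                if fits(centre, semis):
                    target = centre
                    break
        if target is None:
            raise RuntimeError("could not place phantom metastasis; volume too crowded")
        placed.append(Metastasis(centre_um=target, semi_axes_um=semis, code_fractions=req["codes"]))
    return placed


def _mouse_spec(
    rng: np.random.Generator,
    poly_distance_factor: float,
    shape=_COHORT_SHAPE,
    spacing=_COHORT_SPACING,
) -> PhantomSpec:
    ext = tuple((n - 1) * s for n, s in zip(shape, spacing))
    # two z-spanning vessels in opposite quadrants, radii 8–14 μm
    vessels = []
    for qy, qx in ((0.3, 0.3), (0.7, 0.7)):
        radius = float(rng.uniform(8.0, 14.0))
        y = qy * ext[1] + float(rng.uniform(-8.0, 8.0))
        x = qx * ext[2] + float(rng.uniform(-8.0, 8.0))
        vessels.append(Vessel(p0=(0.0, y, x), p1=(ext[0], y, x), radius_um=radius))

    def mono_codes() -> dict[int, float]:
        return {int(rng.integers(1, 8)): 1.0}

    def poly_codes() -> dict[int, float]:
        k = int(rng.integers(2, 4))
        codes = rng.choice(np.arange(1, 8), size=k, replace=False)
        # minority fraction kept ≥ 0.2 so the default presence cutoff recovers it
        w = rng.uniform(0.2, 1.0, size=k)
        fracs = 0.2 + (1.0 - 0.2 * k) * w / w.sum()
        return {int(c): float(f) for c, f in zip(codes, fracs)}

    def mono_gap() -> float:
        return float(rng.uniform(15.0, 45.0))

    def poly_gap() -> float:
        return float(rng.uniform(15.0, 45.0)) * poly_distance_factor

    requests = []
    # equal keeper counts per chromatic class, and a coin-flipped class for
    # the special objects, keep the classes exchangeable under the null preset
    for _ in range(4):
        requests.append({"radius_um": float(rng.uniform(14.5, 20.0)), "gap_um": mono_gap(), "codes": mono_codes()})
    for _ in range(4):
        requests.append({"radius_um": float(rng.uniform(14.5, 20.0)), "gap_um": poly_gap(), "codes": poly_codes()})
    # one object deliberately touching a vessel, class at random
    requests.append(
        {"radius_um": float(rng.uniform(15.0, 19.0)), "gap_um": -4.0,
         "codes": mono_codes() if rng.random() < 0.5 else poly_codes()}
    )
    # one larger object reaching the 'small' size class, mildly ellipsoidal
    if rng.random() < 0.5:
        large_gap, large_codes = mono_gap(), mono_codes()
    else:
        large_gap, large_codes = poly_gap(), poly_codes()
    requests.append(
        {"radius_um": float(rng.uniform(30.0, 34.0)), "gap_um": large_gap,
         "codes": large_codes, "aspect": (0.85, 1.1, 1.05)}
    )
    # sub-threshold decoys (volume well below the 9000 μm³ filter)
    for _ in range(2):
        requests.append({"radius_um": float(rng.uniform(7.0, 10.5)), "gap_um": mono_gap(), "codes": mono_codes()})

    metastases = _place_metastases(rng, shape, spacing, vessels, requests)
    return PhantomSpec(
        shape=shape,
        spacing=spacing,
        vessels=vessels,
        metastases=metastases,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def preset_cohort(
    seed: int,
    poly_distance_factor: float = 0.5,
    n_iv: int = 5,
    n_mfp: int = 4,
) -> list[tuple[PhantomSpec, str, str]]:
    """Two-group phantom cohort mirroring the IV/MFP design (5 + 4 mice).

    ``poly_distance_factor`` scales the vessel gaps of polychromatic
    metastases relative to monochromatic ones: 0.5 places them twice as close
    (the effect preset), 1.0 draws both classes from identical distributions
    (the null preset).
    """
    rng = np.random.default_rng(seed)
    out = []
    for g, count in zip(COHORT_GROUPS, (n_iv, n_mfp)):
        for i in range(count):
            mouse_id = f"{g}{i + 1}"
            out.append((_mouse_spec(rng, poly_distance_factor), mouse_id, g))
    return out
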