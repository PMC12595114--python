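# Methods

This note documents the models, conventions and numerical choices behind
`lobemap`, and what the synthetic-phantom validation does and does not show.

## Geometry conventions

Volumes are arrays indexed `(z, y, x)` with voxel spacing `(dz, dy, dx)` in
µm; the default acquisition geometry is 1.22 µm in xy and ~2.9 µm in z, so z
is ~2.4× coarser than xy. The centre of voxel `(i, j, k)` sits at physical
position `(i·dz, j·dy, k·dx)`. Spacing is a required input — there is no
pixel-unit fallback, because every reported quantity (volumes in µm³,
distances and diameters in µm, areas in µm²) depends on it. A voxel belongs
to a rendered phantom shape iff its centre lies inside the continuous shape,
matching the voxel-centre semantics of the distance transforms.

## Preprocessing

The median filter and the rolling-ball background subtraction operate
slice-wise in 2D with flat disk footprints, because their radii (2 px and
750 px by default) are defined on the fine xy grid of each acquisition
plane. Background subtraction is greyscale opening: `out = max(in −
opening(in), 0)`. The flat-disk opening is exactly specifiable and is tested
against an exhaustive erosion-then-dilation oracle; for radii large enough
that the disk covers a slice from any centre (radius ≥ slice diagonal, which
holds for 750 px on desk-scale slices), the opening degenerates to the
per-slice global minimum and is computed that way — bit-identical and O(N).
Direct openings at intermediate radii cost O(N·r²); practical radii should
be chosen ≫ the structures of interest but, where speed matters, either small
or past the degeneracy bound. Thresholding is inclusive (`≥ t`), the same
keep-at-boundary convention used by the volume filter. Segmentation
thresholds are user configuration: they were tuned by eye on the original
data and no universal value exists.

## Barcode model

The three binary fluorophore masks carry bit values S = 1, V = 2, T = 4; the
per-voxel sum is the barcode code 0–7, with the seven non-zero codes the
seven barcoded populations. The encoder generalises to k channels (2^k − 1
populations). Metastases are connected components of the channel union at
26-connectivity by default (compact blobs; configurable to 6 or 18).
Objects with volume < 9000 µm³ — roughly one cell — are excluded; the
boundary is inclusive, so exactly 9000 µm³ survives. A code counts as
present in an object when it occupies at least `presence_fraction` (default
0.05) of the object's voxels. That veto is the deterministic stand-in for
the manual curation step in which thin misassignment rims caused by
overlapping neighbours were corrected by hand; fully manual reassignment
remains available through a corrections table, which records an audit flag.
An object is monochromatic iff exactly one code is present — a
double-positive code such as SV alone is monochromatic, since BPs are the
seven codes, not the three fluorophores. Two size-class presets exist
because the source analyses bin volumes two ways: four bins
(10⁵–10⁶, 10⁶–10⁷, 10⁷–5×10⁷, >5×10⁷ µm³) and three bins (large = >10⁷).
Bins are half-open `[lo, hi)`; volumes under 10⁵ µm³ are `below_small`.

## Vessel morphometrics

*Distance.* The anisotropic Euclidean distance transform (scipy's EDT with
physical sampling) gives each voxel its centre-to-centre distance to the
nearest vessel voxel. The minimum over a metastasis' voxels is its
edge-to-edge vessel distance: since vessel voxels are at distance zero, the
arg-min voxel lies on the object's vessel-facing edge and the value is
within half a voxel of the true surface-to-surface distance, without any
sub-voxel interpolation. Arg-min ties break to the smallest `(z, y, x)`
object voxel and, among equidistant vessel sites, to the smallest vessel
index, so results are deterministic.

*Diameter.* Local thickness at a point inside the vasculature is the
diameter of the largest sphere containing the point and fitting inside the
vessel mask ("fitting" = containing no background voxel centre, so the
radius available at a voxel equals its interior EDT value). The map is
computed by painting spheres from candidate centres in decreasing-radius
order. Candidates whose ball is contained in a 26-neighbour's ball
(`r(n) ≥ r(c) + |c − n|`) are pruned; containment chains strictly increase
the radius, so every pruned ball is covered by a retained one and the painted
map equals the exhaustive inscribed-sphere computation — asserted against a
brute-force oracle in the tests. The nearest vessel's diameter is read at
the single nearest vessel voxel, not averaged over a neighbourhood: the
minimal deterministic choice.

*Contact area.* The metastasis–vessel surface intersect is counted on
6-neighbour voxel faces: every face of an object voxel whose neighbour is
vessel-and-not-object contributes its physical face area (dy·dx, dz·dx or
dz·dy). This is exact on the voxel geometry and brute-force verifiable; it
overestimates the area of a smooth surface by a bounded orientation factor,
which cancels in within-study comparisons such as mono vs poly.

*Normalisation.* Large metastases are trivially nearer vessels, so distances
are divided by the equivalent-sphere radius r = (3V/4π)^(1/3), giving a
dimensionless, size-independent proximity (invariant under isotropic
scaling).

## Cohort statistics

The sampling unit is the mouse: object metrics are reduced to per-mouse
medians (even counts: mean of the central pair; empty groups are absent,
not zero), and tests compare those — a paired two-sided t-test for
mono-vs-poly within animals, Student's pooled-variance t (Welch optional)
for IV-vs-MFP across groups. Objects are never pooled across mice for
inference. Zero-variance inputs make the t statistic undefined; they are
flagged `degenerate` rather than silently propagated. Shannon diversity
H = −Σ pᵢ ln pᵢ is reported in nats by default (base configurable) over
either biomass fractions (default, matching biomass-composition charts) or
metastasis-count fractions; 0·ln 0 ≡ 0.

## The phantom generator

Phantoms emulate exactly the structure the pipeline assumes: straight
tubular vessels of known radius, non-overlapping ellipsoidal metastases with
assigned barcode content placed at controlled edge-to-edge vessel gaps, a
linear background ramp, and additive Gaussian noise, all driven by one seed
(bit-reproducible). Ground truth — ellipsoid volume 4π/3·abc, barcode set,
edge distance, nearest vessel diameter 2R, contact flag — is computed from
the continuous geometry, never from the render, keeping the oracle
independent of rasterisation. Sphere-to-cylinder edge distances are closed
form (centre-to-segment minus both radii); genuine ellipsoids use a
numerical surface minimisation verified against dense angular sampling.
Polychromatic objects are partitioned into contiguous x-slabs matching the
requested code fractions to ±1 voxel, with minority fractions ≥ 0.2 so the
default presence cutoff recovers the true set.

The cohort preset mirrors the two-group design of the motivating study:
5 "IV" + 4 "MFP" mice, each a 64×128×128 volume at (2.9, 1.22, 1.22) µm —
the z extent chosen so physical depth (~186 µm) matches the xy field
(~155 µm) — with two z-spanning vessels (radius 8–14 µm) and twelve
metastases: four monochromatic and four polychromatic keepers (radius
14.5–20 µm, vessel gaps uniform on 15–45 µm, polychromatic gaps scaled by
`poly_distance_factor`, default 0.5), one vessel-touching object and one
larger mildly ellipsoidal object (radius 30–34 µm, reaching the `small`
size class) each assigned a class at random, and two sub-threshold decoys
(radius 7–10.5 µm, well below the 9000 µm³ filter). Equal keeper counts and
the coin-flipped specials make the two classes exchangeable when the factor
is 1.0, so the null preset is exactly null; placements additionally require
the runner-up vessel to be clearly farther than the target vessel, keeping
the nearest-vessel identity (hence the diameter truth) unambiguous.
Foreground intensity is 200 over a background of offset 15 + ramp 10 with
noise σ = 5; segmentation uses threshold 80 — halfway between background
and signal, so recovery is noise-robust without tuning.

Null calibration runs (hundreds of seeds) skip rendering and take per-mouse
medians directly on the analytic tables; this is the reduced-size mode that
makes 200 cohorts a matter of seconds, while the rendered path is validated
separately by the recovery study.

What passing phantoms does **not** show: robustness to real light-sheet
data's optical blur, clearing artefacts, intensity inhomogeneity, curved and
branching vessels, irregular metastasis shapes, or segmentation-classifier
errors — the phantom tests validate the measurement chain downstream of
segmentation, plus its tolerance to additive noise and smooth background.

## Tolerances and degenerate inputs

Recovered phantom volumes agree with analytic truth within 10 % for objects
of ≥ 500 voxels (rasterisation plus one boundary-voxel layer); vessel
distances and diameters within one voxel diagonal √(dz² + dy² + dx²) ≈
3.37 µm at the default spacing; barcode sets exactly. An empty vessel mask
is a hard error ("no vasculature") since every distance would be infinite;
an empty metastasis mask yields an empty records table; Shannon fractions
must sum to 1 within 1e−9. The paired mono-vs-poly effect test on the
default cohort rejects at α = 0.05 across seeds, and its p-values under the
null preset are approximately uniform (KS check).

## Known limitations

- Vessels are straight tubes in phantoms; the morphometrics themselves are
  topology-agnostic, but curvature effects on local thickness are untested.
- The rolling-ball is a flat-disk opening, not the classic paraboloid
  approximation; differences are negligible when the radius is much larger
  than the objects, as with the 750 px default.
- Contact area is voxel-face area, a known overestimate of smooth surface
  area; comparisons within a study are unaffected, absolute values should
  not be compared across voxel sizes.
- Distances are voxel-centre based; sub-voxel surface localisation is out
  of scope.
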