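# lobemap

Whole-lobe quantification of optically barcoded metastases and their
relationship to the vasculature in 3D light-sheet microscopy volumes.

Cancer cells can be labelled with lentiviral vectors expressing three
fluorescent proteins — tSapphire (S), Venus (V) and tdTomato (T) — whose
combinatorial co-expression yields 2³ − 1 = 7 optically distinguishable
"barcoded populations" (BPs). After whole-organ clearing and light-sheet
imaging of a lung lobe with a fluorescently cast vascular network, every
metastasis in the organ can be segmented, assigned a BP identity, and
measured against the blood vessels. `lobemap` implements that measurement
chain as a reproducible library, for imaging scientists quantifying clonal
dynamics of metastasis at organ scale.

## What it computes

Given the three fluorophore channels and a vessel channel (multipage TIFF or
Zarr, with explicit voxel spacing in µm):

1. **Preprocessing** — slice-wise median filter (radius 2 px) and
   rolling-ball background subtraction (radius 750 px, implemented as
   greyscale opening with a flat disk), then inclusive intensity
   thresholding; pixel-classifier probability maps can be imported instead.
2. **Barcode classification** — bitwise encoding of the binary channels
   (S = 001, V = 010, T = 100) gives each voxel a code 0–7; connected
   components of the channel union are the metastases; objects smaller than
   9000 µm³ (≈ one cell) are excluded; each survivor gets per-code voxel
   fractions, a barcode set (codes occupying ≥ 5 % of the object) and a
   mono/polychromatic class. Manual corrections can be applied from a table.
3. **Vessel morphometrics** — anisotropic Euclidean distance transform for
   edge-to-edge metastasis–vessel distances; local thickness
   (largest-inscribed-sphere diameter) for the nearest vessel's calibre;
   6-neighbour face counting for the metastasis–vessel contact area; and
   distance normalisation by the equivalent-sphere radius
   r = (3V/4π)^(1/3), making proximity size-independent.
4. **Cohort statistics** — per-BP biomass fractions, Shannon diversity
   H = −Σ pᵢ ln pᵢ, mono/poly counts and proportions, per-mouse medians, and
   paired (mono vs poly within mice) or independent (IV vs MFP delivery
   route) two-sided t-tests. The mouse, never the object, is the sampling
   unit.

A synthetic phantom generator (tubular vessels, ellipsoidal barcoded
metastases at controlled vessel distances, background ramp, Gaussian noise)
provides analytic ground truth so the whole chain is testable without any
imaging data.

## Worked example

```python
from lobemap.cohort import default_phantom_config
from lobemap.phantoms import Metastasis, PhantomSpec, Vessel, generate_phantom
from lobemap.pipeline import quantify_lobe

spec = PhantomSpec(
    shape=(32, 96, 96), spacing=(2.9, 1.22, 1.22),
    vessels=[Vessel(p0=(0, 30, 30), p1=(89.9, 30, 30), radius_um=10.0)],
    metastases=[
        Metastasis(centre_um=(45, 70, 35), semi_axes_um=(15, 15, 15),
                   code_fractions={5: 1.0}),            # pure S+T: mono
        Metastasis(centre_um=(45, 35, 80), semi_axes_um=(14, 14, 14),
                   code_fractions={1: 0.6, 2: 0.4}),    # S and V: poly
    ],
    seed=99,
)
channels, truth = generate_phantom(spec)
result = quantify_lobe(channels, default_phantom_config())
for r in result.records:
    print(r.object_id, r.chromatic_class, round(r.volume_um3),
          round(r.nearest_vessel_distance_um, 1),
          round(r.nearest_vessel_diameter_um, 1))
```

prints

```
1 polychromatic 11296 28.1 19.1
2 monochromatic 14218 17.1 19.1
```

i.e. two metastases: the polychromatic one (analytic ellipsoid volume
11 494 µm³, recovered within 1.8 %) sits 28.1 µm from a vessel of local
thickness 19.1 µm (true edge-to-edge distance 26.2 µm, true diameter
20 µm); the monochromatic one (14 137 µm³) lies 17.1 µm away (true
15.3 µm). All geometric errors are below one voxel diagonal (3.37 µm).

The same run is available from the shell:

```bash
lobemap phantom --seed 1 --output scratch/cohort      # synthetic cohort
lobemap validate --config config.yaml
lobemap run --config config.yaml --output out/        # records.csv + summary.json
lobemap stats --records out/records.csv               # cohort statistics
```

## The phantom validation study

The numbered scripts under `analysis/` run the package's validation study on
the synthetic cohort (5 "IV" + 4 "MFP" phantom mice, 64×128×128 voxels at
2.9×1.22×1.22 µm, twelve metastases per mouse, polychromatic objects placed
closer to vessels by a factor 0.5):

```bash
python analysis/01_generate_cohort.py --seed 1    # specs + ground truth
python analysis/02_quantify_cohort.py --seed 1    # full pipeline + error table
python analysis/03_cohort_statistics.py --seed 1  # diversity, tests, calibration
```

Outputs land in `results/cohort/`.

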