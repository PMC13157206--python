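# rtssqc

Quantify what a load/save round trip through a contour-editing system does
to a DICOM RT Structure Set: how far the polygon boundaries move, whether
the topology changes, and how a suite of contour similarity measures is
affected.

The package contains:

- **`rtssqc.rtss_io`** — minimal DICOM RT Structure Set reader/writer
  (explicit VR little endian) with configurable DecimalString precision,
  plus a JSON grid sidecar for structure sets without a referenced image
  series.
- **`rtssqc.model`** — the polygon-stack data model: `PlanarContour`,
  `Structure`, `ImageGrid` (patient millimetres throughout).
- **`rtssqc.preprocess`** — duplicate-vertex and degenerate-contour
  removal, slice grouping and matching.
- **`rtssqc.synthetic`** — analytic test structures (sparse/dense cuboids
  and octahedra, multi-region fixtures) and a simulator of re-export
  behaviours: precision truncation, boundary resampling, 2D/3D mask round
  trips, small-region removal, vertex subsampling/densification.
- **`rtssqc.displacement`** — per-vertex nearest-boundary distances
  (slice by slice), mean/max summaries, cumulative curves in voxel-relative
  units, and topology-change detection from region counts and directional
  asymmetry.
- **`rtssqc.similarity_polygon`** — measures computed directly on the
  polygons: normalised added path length (nAPL) at voxel-relative
  tolerances, volumetric Dice (vDSC) by exact polygon clipping, and the 2D
  distance family (2DHD, 95%2DHD, 50%2DHD, 2DMSD).
- **`rtssqc.similarity_mesh`** — mesh-pathway measures: rasterization,
  signed distance transform, marching-cubes extraction, surface Dice
  (sDSC) at tolerance and 3D mean surface distance.
- **`rtssqc.pipeline`** / **`rtssqc.cli`** — end-to-end experiment
  orchestration and a command-line interface.

## CLI

```bash
# write the six analytic reference/test pairs as RTSS files (+ grid sidecars)
rtssqc generate --out data/ --cube-size 50 --dense-spacing 1

# apply a named simulated re-export behaviour
rtssqc perturb --in data/Object_A_test.dcm --out reexported.dcm --system mask2d

# print the full measure suite for one pair
rtssqc measures --ref data/Object_A_reference.dcm --test data/Object_A_test.dcm

# full experiment from a YAML config
rtssqc analyze --config experiment.yaml --out results/ --plots
```

Example `experiment.yaml`:

```yaml
cube_size: 50
dense_spacing: 1.0
dx: 1.0
dy: 1.0
dz: 2.5
tolerance_fractions: [0.01, 0.1, 0.5, 1.0, 2.0, 3.0]
include_mesh: true
include_multi_region: true
```

`analyze` writes `summary.csv` (one row per structure × simulated system,
with displacement statistics, vertex counts, topology flags and every
measure computed against both the original test contour and the
reference), `measures_by_tolerance.csv`, `cumulative_curves.csv` and a
run `manifest.json`.

## Conventions

- Coordinates are patient millimetres; voxel indices exist only inside
  rasterization.
- A structure of height H has `floor(H / dz) + 1` slices, with both
  z-extremes included.
- Tolerances are expressed as fractions of the in-plane voxel size
  (`min(dx, dy)` when anisotropic); the default sweep is
  1%–300%.
- Cleaning (duplicate vertices, zero-area contours) is applied to both
  members of every comparison by default, so systems that clean during
  re-export are not penalised.
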