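# morphoseg

3D segmentation and morphological quantification of densely packed
embryonic cells from membrane-fluorescence stacks — developed and
validated entirely on synthetic embryo phantoms with exact ground truth.

Early embryos pack tens of cells into a closed ellipsoid; the only
reliable landmark between them is the fluorescently labelled membrane,
which is blurred anisotropically, attenuated with depth, dimmed where
walls run parallel to the optical axis, and noisy. This package
implements a complete pipeline for that setting:

1. **Phantom generation** — synthetic embryos (Voronoi cells inside an
   ellipsoid, 26-connectivity-watertight membranes, realistic imaging
   degradations) with exact label, lineage and morphology ground truth.
2. **Distance-class targets** — the learning target is not a binary
   membrane mask but the discretized distance to the nearest membrane,
   with geometrically shrinking bins that concentrate resolution at the
   walls.
3. **DMapNet** — a small pseudo-3D encoder–decoder (plain NumPy, tape
   autodiff, Adam) predicting per-voxel distance classes under a
   weighted cross-entropy whose inter-class penalty grows exponentially
   with class distance.
4. **Graph-seeded grouped watershed** — h-suppressed relief minima as
   seeds; seed pairs joined by edges weighted by the membrane-crossing
   line integral (zero iff the segment crosses no membrane); clusters of
   membrane-free-reachable seeds flooded jointly on a relief that places
   ridges mid-wall.
5. **Cell identity** — regions named from nucleus lineage records,
   including anaphase sister pairs (resolved to the mother), merge
   detection (honest "lost" flags) and nucleus-free cavity detection.
6. **Morphology atlas** — volume, mesh surface area, the scale-free
   irregularity `eta = sqrt(S)/cbrt(V)` (sphere minimum ≈ 2.1991),
   contact areas with close-packing-derived effective-contact criteria
   (minimum relative area 1/48), cycle-length–volume power laws, sister
   volume asymmetry.
7. **Spatial standardization** — multi-embryo alignment (plane symmetry,
   enclosing-ellipse orientation, cohort rescaling, closed-form
   refinement) and per-cell positional RMSD tables.
8. **Evaluation** — Dice, Hausdorff, Hungarian label unification,
   detection F1 curves, object-level error taxonomy — each backed by a
   brute-force oracle.

Design rationale and the mathematics of each stage are in
[docs/methods.md](docs/methods.md).

## Worked example

`examples/01_segment_phantom.py` runs the core pipeline on an 8-cell
phantom: generate, segment, score against the exact compartment
partition, name every region from the lineage, and tabulate morphology
and contacts.

```sh
python examples/01_segment_phantom.py
```

Output (verbatim):

```text
phantom: 8 cells on a (48, 64, 80) grid, 0.5 um spacing
watershed: 8 regions from 16 seed minima in 9 clusters
per-cell dice: mean 0.9899, min 0.9824
per-cell Hausdorff: mean 0.53 um, max 0.71 um
F1 at IoU 0.50: 1.00, at IoU 0.95: 1.00
naming: 8 regions named, 0 lost; names ['C01', 'C02', 'C03', 'C04', 'C05', 'C06', 'C07', 'C08']

morphology (eta = sqrt(S)/cbrt(V), sphere minimum 2.1991):
cell  volume_um3  surface_um2  eta
 C01     1204.38       637.70 2.37
 C03     1824.25       805.36 2.32
 C06     1029.62       547.82 2.32
 C04     1970.88       854.33 2.33
 C07      940.38       543.23 2.38
 C02     1359.38       663.20 2.32
 C08     1208.38       629.36 2.36
 C05      882.00       524.50 2.39

largest cell-cell contacts:
cell_a cell_b  area_um2
   C03    C07     197.5
   C04    C02     197.5
   C03    C02     178.5

cells fill 98.7% of the embryo ellipsoid (the rest is membrane-assigned rounding)
```

The other examples:

- `examples/02_train_distance_network.py` — trains the tiny DMapNet
  configuration on five phantoms (~2 min on one CPU), shows the loss
  decreasing, and beats the majority-class baseline on a held-out
  phantom.
- `examples/03_atlas_standardization.py` — standardizes five randomly
  posed noisy observations of one embryo into a common frame (per-cell
  RMSD drops from ~10 µm to ~0.4 µm, the injected jitter level) and
  recovers a cycle-length–volume power-law slope.

## Command line

The `morphoseg` entry point exposes the pipeline as thin subcommands
(`phantom`, `targets`, `train`, `predict`, `segment`, `name`,
`quantify`, `contacts`, `evaluate`, `standardize`); run
`morphoseg --help` or any subcommand with `--help`. All scientific logic
lives in the library — the CLI only parses paths and options.

```sh
morphoseg phantom --out work/emb --n-cells 8 --seed 2
morphoseg segment --psi work/emb/membrane_mask.tif --out work/labels.tif
morphoseg evaluate --pred work/labels.tif --truth work/emb/full_partition.tif \
    --out work/scores.csv
```

## Reproduction

Run the full test suite (unit + oracle + acceptance; ~2–3 min on one
CPU):

```sh
python -m pytest tests
```

The acceptance suite (`tests/test_acceptance.py`) holds one test per
acceptance criterion: the analytic and digitized sphere-irregularity
minimum, the 1/48 close-packing fraction, the default network's
24-in/16-out slice contract, five ≥50-instance brute-force oracle
suites, end-to-end 20-cell phantom recovery (IoU ≥ 0.9, full naming,
anaphase and cavity handling), desk-scale training that decreases loss
and beats the baseline, and power-law slope recovery.

The standalone acceptance target is computed from scratch by:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which evaluates the sphere irregularity minimum at several seed-drawn
radii and writes `{"t1": {"value": 2.1991, "n": 8}}` (the value is
radius-free; any seed yields the same 4-decimal result).
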