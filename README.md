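# maizeskel

Curve-skeleton extraction and phenotypic trait estimation from colored 3D
point clouds of maize plants.

Terrestrial laser scans of potted maize deliver dense colored point
clouds, but breeders and modelers need organ-level numbers: how long each
leaf is, how steeply it inserts, where it attaches, how tall the plant
stands. `maizeskel` bridges that gap with a five-stage skeletonization
pipeline and six trait estimators, plus a procedural plant generator that
provides exact ground truth for end-to-end validation.

## Method

Given one registered plant scan (PLY / PCD / XYZRGB), the pipeline runs:

1. **Denoising.** Pot points are removed by a color-difference measure
   D = 2·|max(η_i,η_j)/min(η_i,η_j) − 1|·θ, where η = (r+g+b)/3 is
   brightness and θ the angle between mean-centered chroma vectors scaled
   so a right angle maps to 255; a point matching any sampled pot color
   with D < 0.1 is dropped. Scan noise is removed by near-propagation
   clustering: connected components at radius r = 0.012·l (l the
   bounding-box diagonal), discarding components smaller than half the
   average local point density.
2. **Laplacian contraction.** The cloud is iteratively shrunk by solving
   the stacked least-squares system [W_L·L; W_H]·P^{t+1} = [0; W_H·P^t],
   with L a cotangent Laplacian over tangent-plane Delaunay one-rings,
   W_L a growing contraction weight and W_H,i = W_H,i⁰·S_i⁰/S_i^t
   attraction weights driven by one-ring shrinkage. After a few
   iterations the surface collapses onto stem and vein curves.
3. **Adaptive sampling.** Sparse key points are produced by greedy sphere
   absorption, with smaller spheres where the directionality degree
   l(v) = λ₂/(λ₀+λ₁+λ₂) of the local covariance indicates a junction.
4. **Topological connection.** Key points connect to ≤3 nearest
   neighbors; closed loops are broken by deleting the edge maximizing a
   normalized coplanarity + turning-angle weight; the tree is segmented
   into a stem path (straightest vertical continuation) and leaf
   polylines rooted at growth points.
5. **Calibration.** Stem sections between growth points are straightened
   on total-least-squares lines fitted to the stem's own surface points;
   leaf polylines are re-walked with a cutting plane perpendicular to the
   local tangent, replacing each node by the slab centroid, recovering
   occluded leaf bases by an orthogonal-distance fan fit down to the stem
   axis and missing tips by forward extension.

From the calibrated skeleton, six traits are computed per the standard
conventions: leaf length, leaf inclination angle, leaf top length, leaf
azimuthal angle (counter-clockwise from the lowest leaf), leaf growth
height, and plant height. `evaluate` scores predictions against a
reference with NRMSE (% of the reference mean) and R².

The synthetic module generates maize plants (stem cylinder, quadratic-arc
leaf veins with ribbons, alternate 180°±10° phyllotaxy, Gaussian sensor
noise, optional pot and outlier clutter) together with exact analytic
ground truth, so every stage is testable without field data.

## Worked example

```python
from maizeskel import PlantSpec, make_plant, run_pipeline, PipelineConfig, evaluate

spec = PlantSpec(seed=11, n_leaves=6, noise_sigma=0.001, points_per_plant=6000)
cloud, truth = make_plant(spec)
result = run_pipeline(cloud, PipelineConfig(), plant_id="demo")

print(result.traits.leaves.round(3).to_string(index=False))
print(f"plant height: {result.traits.plant_height_m:.3f} m "
      f"(true {truth.traits.plant_height_m:.3f} m)")
print(evaluate(result.traits, truth.traits).round(2).to_string())
```

prints

```
plant_id  leaf_rank  leaf_length_m  inclination_deg  top_length_m  azimuth_deg  growth_height_m
    demo          1          0.847           28.210         0.276        0.000            0.232
    demo          2          0.754           30.104         0.210      176.035            0.494
    demo          3          0.767           48.201         0.290      349.069            0.718
    demo          4          0.659           39.688         0.305      174.701            0.860
    demo          5          0.791           34.676         0.252      358.101            1.082
    demo          6          0.692           41.535         0.199      179.446            1.416
plant height: 1.576 m (true 1.600 m)
                 n  rmse  nrmse_pct    r2
trait
leaf_length_m    6  0.05       7.08  0.55
inclination_deg  6  1.86       5.17  0.96
top_length_m     6  0.02       6.52  0.84
azimuth_deg      6  0.91       0.44  1.00
growth_height_m  6  0.01       1.36  1.00
plant_height_m   1  0.02       1.53   NaN
```

Each row is one leaf, ranked from the lowest insertion upward: leaf 1
attaches 0.23 m above the stem base, inserts at 28° from the stem axis,
is 0.85 m long along the vein, reaches its highest point 0.28 m of arc
from the base, and defines the 0° azimuth reference; leaves alternate
sides (azimuths near 0°/180°). The evaluation block compares every
recovered trait against the generator's analytic ground truth.

## Command line

```bash
maizeskel synth --seed 1 --n-plants 1 --out scene/       # synthetic plant + truth
maizeskel run --input scene/plant_00.ply --out out/      # full pipeline
maizeskel eval --pred out/ --truth ref/ --out report.json
maizeskel all --seed 1 --out study/                      # study end to end
```

`run` writes the denoised cloud (PLY), the skeleton (JSON), per-leaf and
per-plant trait CSVs, and a per-stage log.

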