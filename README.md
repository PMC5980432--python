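# iseikit

Quantitative measurement of **intracellular sperm–egg interactions (ISEIs)**
in insect eggs from 3D confocal image stacks.

In *Drosophila* and many other insects the entire sperm — including an
extremely long flagellum — enters the egg at fertilization and remains there
through the early syncytial divisions. How that flagellum is shaped and
positioned inside the egg, and how this differs between species,
developmental stages and hybrid crosses, is measurable geometry: the
flagellum is a space curve, and the pronuclei and polar bodies are point
landmarks. `iseikit` implements the full measurement chain:

1. **Masking** — seeded "paint with threshold" selection of each labeled
   structure (flagellum, male/female pronucleus, polar-body cluster) as the
   connected in-range voxel component reachable from operator seeds.
2. **Landmarks** — each nuclear mask is reduced to its arithmetic-mean
   center, axis by axis (two voxels at [3,9,7] and [5,3,7] give [4,6,7]).
3. **Centerline tracing** — the core algorithm: an iterative, directed
   tracer converts the tubular flagellum mask into an ordered polyline.
   Voxels are scored by the number and distance of their masked neighbors,
   candidates ahead of the current direction are weighted by score and by a
   distance kernel around a curvature-adaptive preferred step, each new
   point is a score-weighted neighborhood centroid, and the voxels between
   consecutive points are *consumed* — removed from further consideration —
   which lets the tracer pass cleanly through places where the flagellum
   crosses over itself. Tracing runs in both directions from the seed pair
   and the result is resampled at uniform arc-length spacing.
4. **Shape descriptors** — for a centerline r(s): arc length
   L = ∫|r′| ds; net length |r(L) − r(0)|; aspect ratio L / net length
   (1 for a straight sperm); curvature κ = |r′ × r″| / |r′|³ (the
   reciprocal best-fit-circle radius), with total curvature ∫κ ds and
   average curvature ∫κ ds / L; torsion
   τ = (r′ × r″)·r‴ / |r′ × r″|² (signed local helicity); and the
   open-curve writhe Gauss double integral
   Wr = (1/4π) ∬ (t(s) × t(s′)) · (r(s) − r(s′)) / |r(s) − r(s′)|³ ds ds′.
   Derivatives come from a smoothing-spline fit with a noise-estimated
   default smoothing level.
5. **Positional descriptors** — mean distance from the polar-body center to
   the resampled flagellum points (*sperm positioning*) and the 3D distance
   between the male and female pronuclei; both exist only at the pronuclear
   (PN) stage, before karyogamy.
6. **Statistics** — one-way ANOVAs within species across stages and between
   species per stage, two-way ANOVAs (female origin × male origin, sequential
   SS) for parental vs. reciprocal-hybrid crosses, and Tukey HSD
   (Tukey–Kramer for unequal n) post hoc on significant results.

Because no real stacks ship with the package, a first-class synthetic-scene
generator produces voxel stacks of simulated eggs — line, circle-arc, helix,
figure-8 and random-spline flagella with known analytic descriptors, nuclear
blobs, anisotropic voxel spacing (default z-step 0.002 mm) and additive
noise — so every stage of the chain is validated against exact ground truth.

## Worked example

Simulate a helical flagellum (radius a = 0.01 mm, pitch parameter
b = 0.003 mm, 4.5 turns), rasterize it at the standard anisotropic spacing,
trace the tube back out and measure it:

```python
from iseikit.synth import CurveSpec, SceneSpec, make_curve, rasterize_scene
from iseikit.centerline import trace
from iseikit.geometry import describe_points

spec = CurveSpec("helix", {"radius": 0.01, "pitch": 0.003, "turns": 4.5})
curve = make_curve(spec)
grid, masks, truth = rasterize_scene(SceneSpec(seed=1), curve.points,
                                     curve.descriptors)
poly = trace(masks["flagellum"])
meas = describe_points(poly.points)
for name, value in meas.as_dict().items():
    true = truth.descriptors.as_dict()[name]
    print(f"{name:18s} measured {value:9.4f}   true {true:9.4f}")
```

prints

```
arc_length         measured    0.2834   true    0.2952
net_length         measured    0.0862   true    0.0871
aspect_ratio       measured    3.2859   true    3.3872
average_curvature  measured   96.4729   true   91.7431
total_curvature    measured   27.3367   true   27.0819
average_torsion    measured   30.5390   true   27.5229
writhe             measured    2.5085   true    2.5572
```

Lengths are in mm, curvature and torsion in 1/mm, total curvature in
radians; aspect ratio and writhe are dimensionless. The true values follow
the helix closed forms κ = a/(a²+b²) = 91.74 mm⁻¹ and
τ = b/(a²+b²) = +27.52 mm⁻¹ (positive = right-handed); the traced values
recover them to within a few percent at this voxel resolution, with the
third-derivative quantity (torsion) noisiest — the reason comparative
analyses usually rely on the curvature- and length-based descriptors.

The same chain is available from the shell:

```bash
iseikit pipeline --config config.yaml --seed 3 --out run1
# -> run1/data/*.tif, run1/records.csv, run1/anova.csv
```

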