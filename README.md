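# cellwallfem

Turn brightfield micrographs of plant-stem cross-sections into
two-dimensional cell-wall finite element models, and use them to study how
cell-wall properties set tissue stiffness.

Stalk lodging — the buckling or breakage of crop stems under wind and
gravity — begins at the cellular scale: load is carried by the network of
cell walls in the stem cross-section. `cellwallfem` digitizes a stained
cross-section image into that wall network and solves it as a 2-D beam
frame, giving per-wall stresses and a tissue-level stiffness that can be
related back to microstructural phenotypes (cell size, wall thickness, wall
modulus).

## Pipeline

1. **Preprocess** (`imageprep`): 8-bit conversion, sharpening, a
   brightness/contrast window (default −10…127), and a 3×3 median
   "despeckle" applied three times.
2. **Segment** (`segment`): either an intensity band threshold (default
   0–175, dark walls) with automated speck/hole cleanup, or a trainable
   two-class pixel classifier (random forest over intensity, Gaussian and
   gradient-magnitude features) driven by user scribbles. The wall mask is
   converted to an exact Euclidean distance map (EDM) and thinned so
   neighbouring cells separate.
3. **Tessellate** (`tessellate`): cell interiors are labeled, ultimate
   eroded points (EDM maxima) located, the plane partitioned by
   nearest-interior (Voronoi) assignment, and the boundary skeleton
   vectorized into a planar **wall graph** — junction vertices joined by
   polyline walls, with short Voronoi spurs pruned.
4. **Measure** (`morphometrics`): cell counts, areas in μm², a
   cell-count-normalized size histogram, and a blue→red rank-colored
   rendering.
5. **Model** (`fem`, `inp`): each wall becomes a chain of 2-node
   shear-flexible (Timoshenko) beam elements at a 1 μm seed, with
   rectangular sections (thickness default 4.3 μm — the literature average
   for maize — and unit out-of-plane depth under plane stress). Presets
   apply a 1 μm tension test; the sparse linear frame solution yields
   reactions, tissue stiffness K = ΣF/δ, and per-element von Mises stress,
   exportable as an Abaqus keyword (.inp) file or as a stress overlay on
   the source image.
6. **Sensitivity** (`sensitivity`): +5% forward perturbations of wall
   modulus or wall thickness give linear normalized sensitivities
   S = ((K′−K)/K)/0.05. The modulus sensitivity is exactly 1; the
   thickness sensitivity of a bending-dominated cellular tissue is ≈ 3
   (cubic limit (1.05³−1)/0.05 ≈ 3.15), i.e. 5% thicker walls → ~15%
   stiffer tissue.
7. **Fixtures** (`synthfix`): parametric honeycomb wall graphs with exact
   ground truth, rendered synthetic micrographs (noise + speckle), and the
   Gibson–Ashby closed form E* = (4/√3)·E_s·(t/l)³ as an independent check
   on the solver.

## Worked example

A synthetic 3×4-cell honeycomb (edge 60 μm, walls 4.3 μm) rendered with
noise σ=10, then pushed through the full pipeline:

```python
from cellwallfem import (HoneycombSpec, RenderSpec, honeycomb_graph,
                         render_image, ThresholdParams, band_threshold,
                         clean_mask, interior_labels, voronoi_partition,
                         boundary_skeleton, wall_graph, prune_spurs,
                         graph_to_mesh, apply_bcs, Material, solve,
                         structural_stiffness, element_von_mises)
from cellwallfem.imageprep import despeckle
from cellwallfem.sensitivity import normalized_sensitivity

g_true, truth = honeycomb_graph(HoneycombSpec(rows=3, cols=4))
img, _ = render_image(g_true, RenderSpec(noise_sigma=10.0, seed=1))

p = ThresholdParams(lo=0, hi=175, min_speck_area=25, max_hole_area=25)
mask = clean_mask(band_threshold(despeckle(img, 3), p), p)
interiors = interior_labels(mask)
print(f"cells found: {len(interiors.interior_labels_set())} "
      f"(truth: {truth['n_cells']})")

part = voronoi_partition(interiors)
g = prune_spurs(wall_graph(boundary_skeleton(part), scale=img.scale))
print(f"wall graph: {len(g.vertices)} vertices, {len(g.walls)} walls")

mesh = graph_to_mesh(g, seed_size=1.0, thickness=4.3)
bcs = apply_bcs(mesh, "right_stretch", stretch=1.0)
res = solve(mesh, Material(E=1.0, nu=0.3), bcs)
K = structural_stiffness(res, bcs)
svm = element_von_mises(res, mesh)
print(f"tissue stiffness K = {K:.4g} force/um (per unit depth)")
print(f"max wall von Mises stress = {svm.max():.4g} force/um^2")
for param in ("modulus", "thickness"):
    r = normalized_sensitivity(mesh, Material(), bcs, param, 0.05)
    print(f"S_{param} = {r.S:.3f}")
```

which prints

```
cells found: 12 (truth: 12)
wall graph: 22 vertices, 33 walls
tissue stiffness K = 0.0004485 force/um (per unit depth)
max wall von Mises stress = 0.001256 force/um^2
S_modulus = 1.000
S_thickness = 3.069
```

All 12 cells are recovered from the noisy image; the digitized wall network
encloses 12 faces (33 − 22 + 1). The stiffness is in consistent units
(E = 1 force/μm², per unit depth). The sensitivities say a 5% increase in
wall modulus stiffens the tissue by exactly 5%, while a 5% increase in wall
thickness stiffens it by ≈ 3 × 5% ≈ 15% — the wall-bending signature of
honeycomb-like parenchyma.

The same flow is available from the shell:

```bash
cellwallfem synth --rows 3 --cols 4 --out-dir work/
cellwallfem segment --in work/image.png --out work/mask.png
cellwallfem tessellate --in work/mask.png --scale 1.43 --out work/graph.json
cellwallfem buildfem --graph work/graph.json --out-dir work/fem/
cellwallfem sensitivity --graph work/graph.json --param thickness --out work/s.json
```

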