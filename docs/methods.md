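# Methods

## Scope and model

`cellwallfem` treats the stem cross-section as a two-dimensional cellular
solid: cells are hollow, all load is carried by the cell-wall network, and
each wall is an Euler/Timoshenko beam of rectangular cross-section
(in-plane thickness *t*, out-of-plane depth *d*). The material is a single
homogeneous, linear-elastic, isotropic phase with modulus *E* and Poisson
ratio ν. Under the plane-stress idealization the depth enters only as a
multiplicative factor, so the default *d* = 1 μm makes every reported
stiffness a per-unit-depth quantity.

The solver is linear (small displacement). The prescribed boundary
displacements (1 μm) are small against specimen dimensions of hundreds of
μm, so geometric-nonlinear corrections are second order; the modulus
sensitivity of exactly 1.0 that the linear model produces is the hallmark
of this regime. Turgor pressure, cell-interior material, wall-thickness
variation along a wall, and any 3-D effect are out of scope.

## Image processing and segmentation

The preprocessing chain is the standard interactive-microscopy recipe,
made deterministic:

* 8-bit conversion maps the data range linearly onto [0, 255]
  (half-to-even rounding; constant images map to 0; 8-bit inputs pass
  through).
* Sharpening is the fixed 3×3 kernel (center 12, neighbours −1, divisor 4).
* The contrast window (default −10…127) is a per-image parameter — stained
  sections vary, and the defaults suit Safranin-O maize sections; other
  stains need a different window (e.g. 20…112 for toluidine-blue material).
* Despeckle is a 3×3 median, applied 3 times by default.
* All 3×3 filters replicate edge pixels at the border; effects are
  confined to a 1-pixel rim.

Two segmentation routes share one contract (a boolean wall mask):

* **Band threshold** (inclusive bounds, default 0–175 on 8-bit data) plus
  automated cleanup replacing interactive freehand edits: 8-connected wall
  components with area < `min_speck_area` are removed, then 4-connected,
  fully enclosed background holes with area < `max_hole_area` are filled
  (foreground 8-connectivity with background 4-connectivity is the
  standard digital-topology pairing).
* **Trainable pixel classifier**: a seeded random forest on a documented
  feature bank — raw intensity plus Gaussian-smoothed intensity and
  Sobel gradient magnitude at σ ∈ {1, 2, 4}. Probability ties break
  toward wall. This is a deliberately small, reproducible feature set, not
  a re-implementation of any particular interactive tool.

The Euclidean distance map is exact (scipy's exact EDT, not a chamfer
approximation). The image border does **not** count as background, so
walls touching the crop edge keep their full depth and are not artificially
thinned. Thinning keeps wall pixels with EDM ≥ `thin_keep_min`; how thin
the walls can be made before cells merge is image-dependent, which is why
the threshold is exposed rather than fixed. On noisy images thinning can
break rough walls — for pure cell counting the unthinned cleaned mask is
often the better input, and that is what the noisy-count validation uses.

## Voronoi digitization

Cell interiors are 4-connected non-wall components, labeled in raster-scan
order; labels touching the image edge are flagged (border cells are kept
but known to be partially imaged). Ultimate eroded points are regional
maxima of each interior's EDM; a plateau of equal maxima contributes one
point at its centroid (snapped to the nearest plateau pixel). The Voronoi
partition assigns every pixel to the label of the nearest interior *pixel*
(whole-particle Voronoi, matching EDM-based tools, rather than UEP-seeded
Voronoi; UEPs are still computed for diagnostics and seed export). Ties
break toward the smaller label, implemented with exact integer squared
distances so the rule is bit-reliable and testable against brute force.

The inter-region boundary is drawn on the smaller-label side of each
interface, thinned to unit width, and vectorized: skeleton pixels with ≥ 3
neighbours form junction clusters (one vertex per 8-connected cluster, at
its centroid); maximal paths between vertices become walls, simplified by
Douglas–Peucker at 0.75 px; junction-free loops become single walls with a
coincident end vertex. Dangling walls shorter than `max_len` (default
5 μm) with a free end are deleted iteratively, and degree-2 vertices
*created by a deletion* are dissolved by merging their two walls —
pre-existing degree-2 vertices (e.g. on a closed loop) are preserved.
Straight-walled tissue digitizes well; highly rounded cell morphologies
are a known failure mode of the Voronoi approach and out of scope.

## Finite element model

Each wall polyline is split into ⌈L/seed⌉ equal-arclength 2-node elements
(seed default 1 μm). Elements are shear-flexible Timoshenko beams with the
interdependent-interpolation stiffness matrix (shear parameter
Φ = 12EI/(κGAL²), κ = 5/6 for rectangles, G = E/2(1+ν)); this matrix is
nodally exact for prismatic members, so the tension-test stiffness is
insensitive to the seed size (refinement changes K only at rounding level —
the 1 μm seed is kept for fidelity of the stress field along walls).
Sections are per wall: A = t·d, I = d·t³/12, with t from the wall graph or
the 4.3 μm default — the mean of published maize wall-thickness nominals
{3.7, 6.8, 2.0, 4.6} μm.

Boundary-condition presets select extreme nodes within a band (default
seed/2) of the bounding box:

* `right_stretch` (default; the tension test that defines the sensitivity
  study): left nodes fixed in u_x, the lowest-leftmost of them also in u_y
  (removing the remaining rigid mode without over-constraining), right
  nodes driven +1 μm in x.
* `top_stretch`: bottom fixed in u_y, left/right fixed in u_x, top driven
  +1 μm in y (the stretch direction taken as +y).

Rotations are never constrained. Both presets are provided because both
loading descriptions accompany the method; the right-stretch test is the
one the sensitivity study defines unambiguously.

The sparse system is solved by LU with one iterative-refinement pass.
Structural stiffness is K = ΣF_driven/δ; when all driven DOFs share the
same prescribed value and no external loads act, this is evaluated through
the work identity K = 2U/δ² with the strain energy U summed element-wise —
energy is stationary with respect to solution error and free of the
cancellation a raw reaction sum suffers, which is what lets the modulus
sensitivity come out at 1.0 to ~1e-12. Von Mises stress per element is
max over both ends and both outer fibers of √(σ_ax² + 3τ²) with
σ_ax = N/A ± M(t/2)/I and τ = V/(κA). Equilibrium (Σ reactions + Σ loads
= 0 per direction) holds to ≤ 1e-8 relative and is asserted in tests.

The model exports as an Abaqus keyword (.inp) file — *NODE, *ELEMENT
(TYPE=B21), one *BEAM SECTION (RECT) block per distinct thickness,
*ELASTIC, *BOUNDARY cards in Abaqus DOF numbering (1, 2, 6), one *STATIC
step — byte-stable for identical inputs, with a minimal reader for
round-trip verification. The keyword format was chosen over a CAE script
because it is a documented, parseable text standard.

## Sensitivity study

S = ((K′−K)/K)/δ with a one-sided forward step δ = 0.05 applied
multiplicatively to all walls (modulus ×1.05, or every wall thickness
×1.05 with A and I recomputed). Forward differencing is part of the
procedure's definition, not a numerical shortcut: for a bending-dominated
network K ∝ t³ and the forward quotient is (1.05³−1)/0.05 = 3.1525, which
is why honeycomb thickness sensitivities sit slightly above 3; the
axial-dominated limit is exactly 1 (K ∝ t, the quotient of a linear
function). Measured values on hexagonal fixtures span (1.0, 3.1525] as the
t/l ratio moves between regimes. As δ → 0, S converges to the
log-derivative d ln K/d ln t (checked at δ = 0.05, 0.01, 0.001).

## Synthetic fixtures and oracles

No specimen geometries are distributed with the method, so the reference
model is a parametric honeycomb: rows×cols pointy-top regular hexagons
(vertical left/right edges) of edge length l, all walls of thickness t,
with optional seeded vertex jitter (< 0.3·l) for irregular variants.
Defaults l = 60 μm, t = 4.3 μm put t/l ≈ 0.07, the regime of parenchyma
at 100× magnification. The reference stiffness fixture is 6×6 cells
(~7900 beam elements), chosen as the smallest tiling whose interior is
several cells away from every loaded boundary; the sensitivity studies on
it run in seconds.

Rendering rasterizes walls at a configurable width (default 3 px at
0.7 px/μm) as dark lines (intensity 60) over bright interiors (200), then
adds Gaussian noise and salt-and-pepper speckle under a seed. The
generator emulates the geometry and contrast of stained stem sections, not
their photometric realism: real micrographs have wall-thickness variation,
uneven staining and illumination, torn and overlapping cells, and curved
walls. Passing the synthetic end-to-end checks therefore demonstrates the
correctness of the digitization machinery, not segmentation robustness on
arbitrary field material.

Two independent oracles close the loop:

* brute-force enumeration for the EDM and the Voronoi partition (all-pairs
  nearest-background / nearest-particle search on random instances up to
  32×32, 100 seeds each);
* the Gibson–Ashby closed form for the in-plane honeycomb modulus,
  E* = E_s·(t/l)³·cosθ/((h/l+sinθ)sin²θ) = (4/√3)E_s(t/l)³ at θ = 30°,
  h = l. The FE tension test converts to a modulus via E* = K·W/(H·d)
  using the specimen's bounding extents; on 6×6 tilings it agrees with the
  closed form within 10% at t/l ∈ {0.02, 0.05}, with the deviation
  (finite-specimen boundary layers at the loaded zigzag edges, plus the
  axial/shear wall compliance absent from the bending-only closed form)
  shrinking as walls thin.

## Numerical choices and degenerate inputs

* Rounding is numpy half-to-even throughout the intensity maps.
* Inclusive threshold bounds; lo > hi is rejected.
* All-wall masks (no background) make the EDM undefined and raise.
* A mesh with under-constrained or floating parts raises on the singular
  factorization rather than returning garbage.
* A degenerate stress range (min = max) renders all elements blue.
* Cell-size colors use dense area ranks (ties share a color; a single
  outlier giant cell cannot compress the palette); all-equal areas render
  a single color (blue).
* Histogram bins are equal-width over [min, max] with the right-most bin
  closed; frequencies are counts divided by total cells.
* Seeds: every stochastic component (jitter, noise, speckle, the
  classifier) takes an explicit integer seed and is bit-reproducible.

## Known limitations

Two-dimensional plane-stress idealization; uniform thickness per wall;
linear kinematics; polyline (not curved-spline) walls; border cells are
flagged but still less reliable than interior cells; the trainable
classifier is a compact stand-in for interactive ML segmentation tools and
does not reproduce any specific tool's feature bank or output.
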