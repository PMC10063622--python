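# Methods

`spiralmaze` models a complete mesoscale dispersal assay for minute walking
insects (sub-millimetre egg parasitoids such as *Trichogramma*): a long
corridor wrapped into a double spiral, back-lit and photographed once per
minute, with every dark blob mapped to a signed curvilinear distance from the
release point. This note records the models, the parameters that matter, and
the design decisions taken where the design was genuinely open.

## Maze geometry

The corridor centerline is built from two interleaved Archimedean spirals
joined at the plate center by a point-symmetric S-curve (two semicircles of
radius `r0/2`), so the path is exactly symmetric about the introduction
point: an individual dispersing left experiences the same curvature sequence
as one dispersing right. With corridor width `w` (default 10 mm) and wall
width `v` (default 2 mm), each arm is `r = r0 + c φ` with `c = (w + v)/π`;
interleaving the point-reflected arm gives a constant centerline spacing of
`w + v` along any ray. The inner radius `r0 = 2 (w + v)` keeps the S-curve
clear of the first winding. The circular design is stretched along the
plate's long axis so the spiral envelope fills a non-square plate; walls are
the plate material minus the corridor (the centerline buffered by `w/2`),
computed with shapely.

The default profile is frozen in `DEFAULT_PROFILE`: a 440 × 330 mm plate,
10 mm corridor, 5 mm wall height, 2 mm walls, and 4.74 turns per arm. Wall
width and turn count are not printed anywhere for the physical device; they
were calibrated once so that the generated centerline is 5.75 m (the
documented tunnel length) and then frozen — `default_maze()` yields
5.741 m. Coordinates are millimetres, origin at the plate center, y up;
raster masks use pixel centers at `(i + 0.5)/resolution`.

Rasterization burns the centerline into the pixel grid and thresholds an
exact Euclidean distance transform at `w/2`, then cuts the two end caps
flat; this is fast at any resolution and guarantees a single 8-connected
tube.

### Camera occlusion

A pinhole camera at height `H` above the floor sees past a wall of height
`h` only beyond the projection of its top edge: material at lateral distance
`r` from the optical axis hides a floor strip of width `r·h/(H−h)` on its
far side. The hidden region is computed exactly as the union of the wall
region scaled about the axis by factors spanning `[1, H/(H−h)]` (steps small
enough that consecutive displacements stay below the wall thickness),
intersected with the corridor. A pixel-level ray-casting oracle agrees with
this construction to well under half a percentage point. For the default
geometry (mean corridor radius ≈ 108 mm) with 5 mm walls and a 700 mm
camera the model yields ≈ 6.9 % hidden floor; occlusion grows with radius,
so the per-bin occluded fraction correlates strongly with |s| — both facts
are reported as-is by `occluded_floor_fraction`. Lens focal length affects
only the field of view, not the shadow geometry at fixed camera height.

## Synthetic experiments

The corridor is quasi-one-dimensional (1 cm wide, metres long), so motion is
simulated directly in the signed arc coordinate `s`: per-phase Gaussian
increments with variance `2 D dt` per one-minute step, reflecting at the
tunnel tips, all individuals released at `s = 0`. Phase switches are
synchronous across individuals — a deliberate simplification; nothing in the
assay constrains individual-level switching. Positions are embedded to 2-D
through the centerline with a uniform lateral jitter within ±`w/3`.

Rendering emulates the back-lit optics: a bright tunnel floor (default 200
gray levels) on an illumination field carrying a long-range horizontal
gradient (10 %) and a mild vignette (6 %), dark walls, dark elliptical blobs
(length 0.5 mm, aspect ratio 2.5, contrast 140 gray levels, anti-aliased
edges), additive Gaussian pixel noise (sd 2), 8-bit output. A configurable
fraction of observations (default 1 %) is marked invisible to emulate
concealment behind wall edges. The generator does **not** model defocus,
motion blur, specular reflections, insect posture changes, or interactions
with hosts; a passing pipeline therefore demonstrates correctness of the
computational chain under controlled optics, not performance on real
footage.

Simulation studies use a compact maze — same corridor width, wall width and
construction as the full device, ~0.62 m of tunnel in a 150 × 112 mm plate,
rendered at 4 px/mm (the smallest resolution at which a 0.5 mm insect still
spans the required 2 px) — so that a full 360-frame, 200-individual
experiment runs in seconds. These are the package's chosen problem sizes for
its own verification experiments.

## Detection

Frames are processed in non-overlapping packs (default 60): the pack
background is the per-pixel temporal median (insects move, so the median is
particle-free; the mean is available by configuration), each frame is
subtracted from the background in floating point so that dark insects give a
positive difference, the difference is thresholded (a config value — the
original workflow sets it by eye; Otsu is available but off by default), and
8-connected components within an area range become records with four shape
descriptors.

Descriptor conventions, fixed and documented because they shift values by a
few percent between tools: perimeter is the count of exposed pixel edges
scaled by π/4 (Cauchy–Crofton), circularity is `4πA/P²` clipped to [0, 1]
(≈ 1 for a rasterized disk), solidity divides pixel count by the area of the
convex hull of the pixel-square corners, and aspect ratio is the
moment-ellipse major/minor axis ratio (a 1/12 pixel-variance term keeps it
finite for thin regions; a degenerate single-row region reports infinity).

Detection is exactly invariant to any global additive illumination change,
since only the background-minus-frame difference enters.

## Linearization (skeleton fragmentation)

The corridor mask is thinned to a 1-px curve; side branches shorter than
twice the grid spacing are pruned, with true branch points identified by the
crossing number of the 8-neighborhood (plain degree counting misreads the
L-corners of a digital curve as junctions). Thinning erodes about half the
corridor width at each tip, so both endpoints are extended along the local
tangent to the mask boundary.

The traced pixel chain is cut wherever it crosses a square grid (default
spacing: half the corridor width in px), the fragment nearest the
intersection of the plate diagonals seeds the ordering, and cumulative arc
length is assigned outward along both arms; the arm leaving the center
toward +x carries positive `s` (configurable, recorded in the output
metadata). Fragment spans are half-open and tile the path exactly.

Raw 8-connected chain length (1 per orthogonal step, √2 per diagonal)
overestimates a smooth curve's length by up to ~8 % (staircase bias), which
would dilate all arc coordinates and hence MSDs. Arc positions are therefore
measured on a 5-px moving average of the pixel trace, which matches the
generating centerline length to ~0.3 %; the raw signed chain distance is
retained alongside (`s_chain_px`) as a diagnostic.

Detections are projected orthogonally onto the nearest skeleton segment
(KD-tree candidate, exact point-to-segment refinement; ties break toward
smaller |s|), giving the signed arc coordinate and the unsigned
perpendicular offset. A quantized variant returning the fragment's central
distance is available behind a flag. Round-trip error (embed at `s`, render,
project back) is below 1 mm for 95 % of positions at 4 px/mm.

## Cleaning filters

Four pure predicates, applied in a fixed order (redundancy → size → edge →
shape) so the removal counts are attributable; membership is
order-independent. Thresholds are toolkit defaults, not published values:

- **redundancy** — a position rounded to 2 px that recurs in more than half
  of all frames is a static artifact (dust, glued host eggs); insects pause,
  but rarely for half the experiment.
- **size** — area within [15, 120] px² at 16 px/mm (derived from the
  rendered insect size; scale with resolution²).
- **edge** — perpendicular offset at most 0.9 × half corridor width,
  removing wall-shadow artifacts hugging the corridor boundary.
- **shape** — circularity at least 0.4; insects are compact, streaks are
  not.

## Dispersal statistics

MSD at time `t` is the mean over detections (unlinked between frames — no
identity tracking) of `s²` about the introduction point, not the sample
mean: individuals are released at `s = 0` and the distribution stays
centered by symmetry, so MSD equals the positional variance; if the mean
drifted the two would diverge. Frames without detections yield missing
values. Per-minute MSDs are averaged over non-overlapping 15-minute windows
(360 minutes → 24 points); the window length follows the original
autocorrelation criterion — lag-1 residual autocorrelation per regression
segment is computed with its 1.96/√n bound, and a larger window can be
chosen if it flags.

Phase structure is modelled by the continuous hinge family
`y = β₀ + β₁ t + Σ δₖ (t − ψₖ)₊` with 0–2 breakpoints. Conditional on the
breakpoints the model is linear, so breakpoints are estimated by exhaustive
grid search (default resolution: a quarter of the median time spacing;
candidates must leave ≥ 2 points per segment), giving a deterministic global
optimum; batched normal equations keep the 2-breakpoint search to
milliseconds at n = 24. The grid optimum matches a multi-restart iterative
linearization to within 1 % RSS.

Model selection uses nested F tests at α = 0.05 (each breakpoint adds two
parameters), choosing the most complex model that significantly improves on
the simpler ones; an S-shaped series can reject 0-vs-2 while 0-vs-1 fails,
so that comparison acts as an escape. Two eligibility guards protect the
selection against a statistical feature of group-level MSDs: because the
same individuals are measured at every time, the MSD error is long-range
autocorrelated (corr ≈ √(s/t)·(s/t)-like, i.e. a slowly wandering apparent
slope of relative magnitude √(2/n) ≈ 10 % at n = 200), which makes formally
significant micro-breakpoints common under pure diffusion. A candidate model
is eligible only if (1) each phase spans at least 15 % of the experiment and
(2) every slope change is material — relative change of at least 0.6 between
consecutive segment slopes. Both thresholds are fixed defaults, chosen once
against simulated single-, two- and three-phase dispersal; with them, true
phase structures (rate changes of 5–10×) are recovered in ≥ 90 % of
simulated runs per type while iid-noise linear series are classified
diffusive in ≥ 90 % of runs.

Labels follow the slope pattern of the selected model: no breakpoint →
type 1 (diffusive, MSD slope ≈ 2D); one breakpoint with a faster second
phase → type 2 (latency then spread); two breakpoints with a faster middle
phase → type 3 (latency, spread, slow-down); anything else → other.

Validation statistics: detection rate with exact Clopper–Pearson intervals
(rates above 1 are legal and flagged); chi-square homogeneity on shared
spatial bins (bins empty in both samples dropped, df = k − 1); a Monte-Carlo
skewness test of distribution symmetry (sample `b₁ = m₃/m₂^{3/2}` against
simulated Gaussian nulls of equal n, two-sided, seeded; the null is reusable
across repeated tests at fixed n); per-minute ANOVA or skewness screens with
Bonferroni correction over minutes; and a sequential (type I) ANOVA variance
partition returning SST(strain)/(SSR + SST(strain) + SST(others)) with
strain entered last (0/0 → 0 by convention).

## Numerical and degenerate-input conventions

Centerlines are sampled at 0.2 mm chords (arc-length error < 0.01 %).
Breakpoint ties in the grid search resolve toward smaller positions.
Zero-variance samples are rejected by the skewness test; all-empty
contingency tables and zero manual counts raise. 16-bit TIFF input is
rescaled into the 8-bit range. A trailing detection pack with fewer than two
frames is merged into the previous pack.

## Known limitations

- The occlusion model is geometric only; it ignores refraction through the
  top plate and treats wall faces as opaque occluders, and its prediction
  for the default device (~7 %) exceeds the area loss measured
  photographically on the physical device, where bright wall faces partly
  compensate the hidden strips.
- No identity linking: statistics treat detections as exchangeable samples,
  so per-individual quantities (speeds, turn rates) are out of reach.
- The classifier's materiality and minimum-phase-length guards trade
  sensitivity to genuinely small or short rate changes for calibration at
  single-run noise; screens of replicate-averaged series can lower both.
- The synthetic generator's simplifications (synchronous phase switching,
  uniform lateral jitter, position-independent concealment) mean detection
  rates on real footage will differ from the near-perfect rates achieved on
  clean renders.
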