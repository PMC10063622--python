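# spiralmaze

Toolkit for studying the dispersal of minute walking insects — sub-millimetre
egg parasitoids such as *Trichogramma* — in a **double-spiral maze**: a long
corridor (metres) wrapped into two interleaved spirals that fit a single
camera frame, with the release point at the center so both dispersal
directions are topologically identical. The package covers the whole assay
at the desk:

- **design** the maze (parametric double spiral, SVG template for laser
  cutting, camera-occlusion model);
- **simulate** per-phase diffusive dispersal and render ground-truthed,
  back-lit image sequences;
- **detect** insects by pack-wise temporal-median background subtraction and
  connected-particle analysis with shape descriptors;
- **linearize** detections to a signed curvilinear coordinate `s` via
  skeleton fragmentation (skeletonize the corridor, cut the skeleton on a
  grid, order fragments outward from the center, orthogonally project);
- **filter** artifacts (redundancy, size, edge distance, circularity);
- **analyze** dispersal with mean squared displacement (MSD) series and
  piecewise regression.

The statistical core: for a group released at `s = 0`,
`MSD(t) = ⟨s²⟩` grows as `2Dt` under simple 1-D diffusion with coefficient
`D`. Departures are captured by the continuous hinge model

    MSD(t) = β₀ + β₁ t + Σₖ δₖ (t − ψₖ)₊ ,   k ≤ 2,

with breakpoints `ψₖ` found by exhaustive grid search and compared by nested
F tests; the selected slope pattern classifies the dynamics as **type 1**
(diffusive), **type 2** (latency then fast spread), **type 3**
(latency, fast, slow-down), or **other**. Validation statistics (exact
binomial detection-rate CIs, chi-square homogeneity of spatial
distributions, Monte-Carlo skewness symmetry tests, Bonferroni-corrected
per-minute screens, ANOVA variance partition across strains) are included.

See `docs/methods.md` for models, assumptions and design decisions.

## Worked example

A two-phase experiment (latency `D = 0.5 mm²/min` for 2 h, then
`D = 5 mm²/min` for 4 h; 200 individuals, one frame per minute), simulated
and pushed through the full pipeline on a compact maze:

```python
from spiralmaze import DispersalModel, DetectionParams, default_maze, occluded_floor_fraction
from spiralmaze.pipeline import run_synthetic_experiment, compact_maze

g = default_maze()
print(f"tunnel length: {g.arc_length/1000:.3f} m")
occ = occluded_floor_fraction(g, wall_height=5.0, camera_height=700.0)
print(f"hidden floor: {100*occ.occluded_fraction:.1f} %")

model = DispersalModel(phases=((120.0, 0.5), (240.0, 5.0)),
                       n_individuals=200, seed=42)
res = run_synthetic_experiment(model, geometry=compact_maze(),
                               detection=DetectionParams(area_min=1.0, area_max=400.0),
                               n_frames=360)
c = res.classification
print(f"dispersal type: {c.label}")
print(f"breakpoints (min): {[round(b,1) for b in c.selected.breakpoints]}")
print(f"phase slopes (mm^2/min): {[round(s,2) for s in c.slopes]}")
```

prints

```
tunnel length: 5.741 m
hidden floor: 6.9 %
dispersal type: type2
breakpoints (min): [120.5]
phase slopes (mm^2/min): [0.86, 11.08]
```

The default maze reproduces the physical device (a 5.75 m corridor in a
440 × 330 mm plate). The classifier recovers the generating phase structure:
the breakpoint lands on the true switch at 120 min, and the two fitted MSD
slopes bracket the theoretical `2D` values (1 and 10 mm²/min) to within the
sampling noise of a single 200-individual run. The hidden-floor figure is
the geometric pinhole-occlusion prediction for 5 mm walls under a 70 cm
camera.

## Command line

Each stage is a subcommand writing plain CSV/JSON/TIFF artifacts plus a
manifest (`spiralmaze design|simulate|detect|linearize|filter|analyze|
validate|all`), e.g.

```bash
spiralmaze design --out build/
spiralmaze all --config config.yaml --seed 7 --frames 360 --out run/
spiralmaze validate --positions run/filtered.csv --truth run/truth.csv --out run/
```

`validate` compares pipeline output against a ground-truth CSV: detection
rate with its exact binomial CI and a chi-square homogeneity test between
the true and detected spatial distributions.

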