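# nanospring

Mechanical and topological analysis of DNA-origami nanosprings:

- **`nanospring.models`** — extensible worm-like-chain (WLC) mechanics for
  dsDNA handles, Hookean nanospring law, the combined construct model
  `x(F) = x_WLC(F − F0) + (F − F0)/k + x0`, and junction chemo-mechanical
  force estimators (bridge-duplex tension at contour length, G-quadruplex
  bending force, ssDNA linker end-to-end span).
- **`nanospring.ramp`** — two-stage fitting of the WLC+Hooke model to
  force-extension traces (stage 1: force-offset calibration on sub-2 pN data
  with parameters held at theory; stage 2: free nonlinear least squares on
  extension residuals), plus signed stretch/relax hysteresis areas.
- **`nanospring.jump`** — force-jump trace segmentation into
  recoiling/uncoiling events, per-event ΔL / time-to-equilibrium / rate
  measurement, and Hooke spring constants from two force regimes bifurcated
  at ≈2 pN.
- **`nanospring.afm`** — AFM height-map analysis: ridge skeleton tracing,
  least-squares circle fits for curvature radius, turn counting, bilinear
  section profiles, uphill-slope regression, and the crossing-point
  slope-difference chirality call (slope_AB − slope_CD > 0 ⇒ right-handed).
- **`nanospring.trajectory`** — oxDNA topology/configuration parsing
  (0.8518 nm, 3.03 ps per reduced unit), no-superposition RMSD, windowed
  RMSF, 26-entity → 13 guide-point reduction, total-least-squares helix
  fitting (axis, radius, pitch, turns, handedness), and backbone-vs-pier
  radius comparison.
- **`nanospring.synthetic`** — seeded generators for every input class:
  WLC+Hooke force-extension pairs with optional unfolding hysteresis,
  bilinear-law exponential-relaxation force-jump traces, rendered
  crossing-bundle height maps of chosen handedness, helical point clouds,
  and fluctuating pseudo-trajectories (with an oxDNA writer).

## CLI

```bash
nanospring fit-ramp --trace trace.tsv --init theory.cfg --range 0.1:8.2
nanospring jump --trace jump.tsv --breakpoint 2.0 --out-events events.tsv
nanospring afm-chirality --image scan.txt --pixel-size 1.0 \
    --line-ab 60,20:100,140 --line-cd 20,60:140,100
nanospring helix-fit --points guide_points.tsv
nanospring traj-stats --top sim.top --conf sim.conf --rmsf-window 2000:3000
nanospring simulate {ramp|jump|afm|helix|traj} --config spec.cfg --seed 1
```

Traces are TSV (`time_s, force_pN, extension_nm[, direction]`); parameter
sets use a flat `name = value` config format; AFM images are float TIFF or
whitespace text matrices in nm. All forces are pN, lengths nm, energies
pN·nm.

## Notes

- The combined model has an exact degeneracy: the handle stretch term
  `L0·F/K0` and the spring term `F/k` are both linear in force, so only
  `L0/K0 + 1/k` is identifiable.  The default fit holds the handle
  persistence length (a literature constant for dsDNA) and reports the
  K0/k split at the initialisation; `fit_construct(..., hold=())` frees
  everything.
- RMSD deliberately applies no superposition — a rigid 5 nm translation
  reads as exactly 5 nm.
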