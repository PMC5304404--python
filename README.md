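# bfprobe

Headless analysis of **Biomembrane Force Probe (BFP)** videomicroscopy
recordings: tracks the probe bead and the micropipette tip frame by frame,
converts the red-blood-cell (RBC) deformation into a calibrated force time
course, and reports quality metrics, calibration uncertainty and curve
summaries — with a synthetic scene generator so the whole pipeline is
testable against exact ground truth.

## Who this is for

The BFP uses a pipette-aspirated red blood cell as a calibrated spring: a
bead glued to the cell apex contacts the system under study (a single
molecular bond, a cell surface, an axon), and the force transmitted through
the bond deforms the cell.  The technique covers roughly 0.1–1000 pN.
Experiments are repeated many times under imperfect conditions — drifting
focus, littered fields, freely moved pipettes — so the practical bottleneck
is robust *post-hoc* image analysis of the recordings.  `bfprobe` is a
library plus command-line tool for exactly that step.

## The model

In the linear elastic regime the probe is a spring,

    F(t) = k · Δx(t),      Δx(t) = x(t) − x₀,

where `x(t)` is the distance between the bead centre and a fixed anchor
point on the pipette tip, and `x₀` is that distance in a reference frame
with the cell under zero load.  The stiffness follows from
micropipette-aspiration mechanics:

    k = R_p ΔP · π / (1 − R̂_p) / [ ln(4 / (R̂_c R̂_p)) − (1 − ¼ R̂_p − ⅜ R̂_p² + R̂_c²) ]

with `R_p` the pipette radius, `R_c` the bead–cell contact radius, `R_0`
the aspirated-cell radius (`R̂ = R/R_0`), and `ΔP` the aspiration pressure.
Radii in µm and pressure in Pa give `k` directly in pN/µm.  The linear
relation holds for |Δx| ≲ 0.5 µm; beyond that the force is overestimated
and frames are flagged.

Tracking works on two complementary detectors:

* **bead** — circular Hough transform with gradient-directional voting
  (two-stage and phase-coding variants pooled), candidates scored by
  accumulator value divided by a distance factor
  `f_i = max(d_i, R_<) / R_<` penalising jumps; sub-pixel centres from the
  accumulator peak neighbourhood.  Robust to partial occlusion of the rim.
* **pipette tip** — normalized cross-correlation of a user-delineated
  template, refined to sub-pixel by an elliptical-paraboloid fit of the
  correlation peak; template dilation/erosion recovery when the
  correlation collapses.  Typically an order of magnitude more precise
  than the bead.

Recordings that cannot be tracked end-to-end are analysed as a **chain of
disjoint intervals**, sharing patterns and reference frames where focus
recovers, or using local patterns plus manual force offsets where it does
not.  Contrast metrics (SD2, per-frame intensity SD normalized to the
course maximum; rSD2, its running SD) locate the problematic stretches.

## Worked example

Generate a synthetic 456-frame recording (65 fps, 0.1 µm/px) with known
ground truth, track it, and calibrate the probe:

```
$ bfprobe synth basic . --seed 0
wrote basic.tif (456 frames) and basic_truth.csv

$ bfprobe track run.json
wrote out/results.csv
wrote out/session.json
wrote plots to out

$ bfprobe calibrate --rp 1.0 --rc 0.75 --r0 2.5 --dp 200
k = 406.433 pN/um
delta k = 21.5 % (relative, first-order propagation)
```

where `run.json` names the video, the bead seed and radius window, the
pipette pattern rectangle, the interval chain with the zero-load reference
frame `t0`, and the probe geometry:

```json
{
  "video": "basic.tif",
  "bead": {"seed": [142.0, 60.0], "r_min": 9, "r_max": 15},
  "patterns": [{"id": "tip", "frame": 0, "rect": [40, 46, 26, 29], "anchor": [20.0, 14.0]}],
  "intervals": [{"first": 0, "last": 455, "pattern": "tip", "t0": 0}],
  "geometry": {"R_p": 1.0, "R_c": 0.75, "R_0": 2.5, "dP": 200.0},
  "output_dir": "out",
  "export": {"csv": true, "plots": true, "session": true}
}
```

The exported CSV carries one row per frame — positions in px, tracking
metrics `M_b`/`M_p`, contrast metrics, and the calibrated deformation and
force:

```
frame,time_s,interval,bead_x_px,bead_y_px,bead_r_px,M_b,bead_flag,pip_x_px,pip_y_px,M_p,...
0,0,0,141.88945,59.9672407,11.8664158,1.59747271,ok,60.0454066,59.9996255,1,...
```

Against the generator's ground truth this run localizes the bead to
0.082 px RMSE (8.2 nm at 0.1 µm/px) and the pipette anchor to 0.058 px
(5.8 nm); the final frame reads Δx = 0.279 µm, i.e. F = 113.4 pN at
k = 406.4 pN/µm, and the running SD of the force (40-frame window) has a
median of 9.1 pN — the empirical force uncertainty ε_F.  A loading-rate
estimate comes from `bfprobe fit out/results.csv --model line`.

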