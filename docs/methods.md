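# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `bfprobe`, in the order the analysis runs.

## Video access and units

All readers normalize intensities to [0, 1] by the container's *nominal*
maximum (255 for 8-bit, 65535 for 16-bit), never by per-frame min/max: the
SD2 contrast metric compares intensity spread *across* frames and would be
flattened by per-frame stretching.  Colour input is collapsed with ITU-R
BT.709 luminance weights (0.2126, 0.7152, 0.0722).  Coordinates are
0-based `(x, y) = (column, row)` with y growing downward; sub-pixel
positions are real-valued in that frame.

TIFF has no standard framerate tag.  Stacks written by this package embed
`fps` and `pixel_scale` in a JSON ImageDescription, which `open_video`
reads back; for third-party files the framerate stays unset unless
supplied, and any time-dependent operation on such a source fails with an
explicit error rather than guessing.  The pixel scale (µm/px) comes from
`calibrate_scale(known_length_um, measured_length_px)` — a scale bar or
the pipette outer diameter measured once.

## Contrast metrics

SD2 is the per-frame population SD of pixel intensities normalized by the
maximum over the processed course; frames below 0.95 are flagged (focus
loss, probe separation, field changes all reduce intensity spread).  rSD2
is the running SD of SD2 over a centred, edge-truncated window (default
40 frames), normalized by its maximum; it highlights *fluctuating*
contrast, which perturbs template matching more than a stable focus
offset.  Two choices the metric definition leaves open are fixed as:
population (not sample) SD — frame pixel counts make the difference
negligible but oracle tests need one convention — and a centred (not
trailing) window, which localizes contrast events symmetrically.  When an
analysis chains several intervals, the normalization maximum is taken over
the union of processed intervals so the chained courses remain mutually
comparable.  The metrics are advisory: frames are flagged, never excluded
automatically; choosing interval boundaries is the analyst's decision.

## Bead detection

Candidates come from a circular Hough transform over an integer radius
grid `[R_<, R_>]`, computed on Canny edges of the region of interest.
Votes are cast along each edge pixel's intensity gradient (both senses, so
dark and bright beads work alike), at distance r for every trial radius.
Two accumulator variants share that single vote pass and their candidate
lists are pooled (duplicate centres within 1 px keep the higher score):

* **two-stage** — one 2-D array per trial radius; the radius is read off
  the winning layer;
* **phase-coding** — one complex 2-D array for the whole range; the vote
  weight `exp(2πi·k/n_r)` encodes the trial radius, votes at the true
  radius add coherently, and the radius is decoded from the phase at the
  peak.

Gradient-directional voting is essential for occlusion robustness: with
undirected whole-circle voting a half-occluded rim is explained almost as
well by a smaller circle with a shifted centre (higher score per unit
perimeter), which misplaces the centre by pixels.  Rim normals converge
only on the true centre, so the directional peak survives occlusion of
more than half the rim with an error well under a pixel.

Scores are pooled over the 3×3 peak neighbourhood (a circle centred
between pixels splits its votes over adjacent cells; the box sum makes the
score independent of the sub-pixel phase) and normalized by the ideal rim
vote count 2πr.  On the synthetic reference scene this calibration puts a
clean, fully visible rim at ≈ 1.3–1.8, a half-occluded one at ≈ 0.5–0.65,
and pure noise below 0.3; the default gates — candidate floor 0.3,
acceptance threshold M_b ≥ 0.8 — keep their intended meaning (accept clean
detections, flag degraded ones, never admit noise).  Sub-pixel centres are
the vote-weighted centroid of the background-subtracted 3×3 peak
neighbourhood.

Per frame the detector searches a square region of side 4·R_> centred on
the last confirmed centre (the seed for the first frame).  Candidates are
scored as `M_b,i / f_i` with the distance factor
`f_i = max(d_i, R_<) / R_<` (Euclidean `d_i` from the previous centre);
ties break toward the nearer candidate, then the larger radius.  When the
winner stays below threshold, refinement first regrows the region by 50%,
then raises the edge sensitivity one step (0.05).  A frame that still
fails is logged: if a candidate exists it is flagged `low_metric` and
tracking proceeds from it; if nothing is recognizable the frame is flagged
`failed` and the previous centre is kept.  Five consecutive `failed`
frames (configurable) abort the track with a report naming the first bad
frame; the partial track is returned.

## Pipette detection

The tip template (a user-delineated rectangle, with an anchor point
defaulting to the template centre) is matched by normalized
cross-correlation in a restricted region around the last matched position
— the template rectangle inflated by half the template size per side,
regrown by 50% on refinement.  The integer peak is refined by a
least-squares fit of the axis-aligned elliptical paraboloid
`z = a + bx + cy + dx² + ey²` over the 3×3 neighbourhood; the vertex
`(−b/2d, −c/2e)` is the sub-pixel offset, clamped to (−1, 1) per axis (an
out-of-cell vertex indicates a distorted surface, not a real offset).
The five basis monomials are linearly independent on the 3×3 grid, so any
surface of that exact form is recovered exactly; least squares (rather
than exact 5-point interpolation) buys noise averaging from all 9 samples.
Non-concave fits (d or e ≥ 0) and border peaks return zero offset with a
flag.

When the correlation falls below threshold (M_p < 0.95 by default) the
tracker regrows the search region, then attempts **pattern recovery**: the
current pattern must still localize in the interval's initial frame
(M_p ≥ threshold; within 1 px of the cut position when that frame is the
pattern's own source), then rectangle variants with margins of ±2 and
±4 px per side are cut from the initial frame and the best-correlating
variant in the problem frame wins.  Margins are small relative to typical
tip templates and cheap (5 variants including the original).  A successful
recovery replaces the working pattern from that frame onward within the
interval — never retroactively.  Failure semantics mirror the bead's.

The pattern matching pools information from every template pixel, so the
anchor localization is typically several times more precise than the bead
centre; on the synthetic reference scene the anchor RMSE is ≈ 0.06 px
(6 nm at 0.1 µm/px) versus ≈ 0.08 px for the bead.

## Probe mechanics and calibration uncertainty

Stiffness, deformation and force follow the spring model stated in the
README.  Distances are full Euclidean anchor–bead distances by default
(equal to the axial extension under the axial assumption, and degrading
gracefully off-axis); an x-axis-projected option exists.  Sign convention:
Δx > 0 is extension, Δx < 0 compression.  Frames with |Δx| > 0.5 µm are
flagged as outside the linear regime; the value is still reported (it is
the best available number) with the caveat that it overestimates the
force.

When geometry or a valid reference frame is missing, the model falls back
to *generic* mode: a built-in typical geometry (R_p = 1.0, R_0 = 2.5,
R_c = 0.75 µm, ΔP = 200 Pa, giving k̃ = 406.43 pN/µm) and/or the first
processed frame as reference, with the whole course marked uncalibrated —
the shape of the force course is then meaningful, its absolute scale is
only an order of magnitude.

Calibration uncertainty propagates first-order: independent Gaussian
errors σ_R on each radius (default 0.1 µm, i.e. 0.2 µm per diameter at
optical resolution) and σ_P on the pressure (default 5 Pa) in quadrature
through the stiffness formula, with partials by central finite differences
(relative step 1e-4).  At the typical geometry this yields δk = 21.5%
(the pipette-radius term dominates at 19.7%; the pressure term is exactly
σ_P/ΔP = 2.5% since k is linear in ΔP).  A 10⁵-sample Monte-Carlo
propagation agrees with the first-order number within a few percent
relative, so higher-order terms are negligible at these uncertainty
levels.

## Interval chains and the pipeline

An analysis is an ordered set of disjoint frame intervals, each binding a
pipette pattern, a bead seed (explicit, or `"continue"` = the previous
interval's last confirmed centre) and an optional reference frame `t0`.
Validation enumerates *all* problems at once (overlaps, out-of-range
frames, dangling pattern ids, an inheriting first interval).  The
effective reference resolves in order: the interval's own `t0` → a frame
tracked in any other interval of the chain (shared calibration across
gaps) → first-frame fallback, uncalibrated.  An uncalibrated interval can
instead be aligned manually through its additive `offset_pN`.  Frames are
read once per interval into a buffer shared by both trackers.  Gaps carry
no data — no interpolation.  Tracking aborts produce a partial result with
a report; the pipeline never raises on bad frames.  Every flagged frame
(low contrast, low metric, recovery, nonlinear regime) appears in the
result's warnings list, which the CLI also logs to stderr.

Sessions serialize the complete analysis state (chain, patterns including
templates, all tracks, contrast and force courses, report) to a single
versioned JSON document; the video is referenced by path, not embedded.
JSON floats round-trip exactly, so a reloaded session re-exports a
byte-identical CSV.  CSV exports use 9 significant digits for the same
reason.

## Curve analysis

* **Line fit** — least squares; the slope of force vs time is the loading
  rate.
* **Exponential fit** — `y = c + a·exp(−t/τ)` with an explicit offset
  (force plateaus rarely relax to zero), initial guess from
  log-linearization of the tail-anchored residual, solved by nonlinear
  least squares; non-convergence and constant input come back flagged,
  never raised.
* **Plateau detection** — a frame is marked when, over its centred window
  (default 40 frames), the fitted drift |slope|·window_duration and the
  window SD both stay within tolerance; default tolerances derive from the
  series' own noise floor (median running SD ×1.0 for drift, ×1.5 for SD).
  Marked runs merge across gaps shorter than half a window — the
  per-window slope statistic fluctuates at a sizeable fraction of the
  noise floor, so isolated excursions would otherwise fragment genuine
  plateaus — and runs shorter than `min_length` (default one window) are
  discarded.  No reference procedure is specified for this step anywhere;
  this algorithm is the package's own, with every parameter exposed.
* **Running SD** — centred, edge-truncated, population SD; on plateau
  intervals it estimates the deformation uncertainty ε_Δ and thereby
  ε_F = k·ε_Δ.  Only frames whose full window fits inside a plateau
  contribute, which makes the estimate nearly independent of the window
  size (10–100 frames) — windows straddling a manipulation would otherwise
  dominate it.

## Synthetic scenes

The generator renders what the trackers actually see: a dark anti-aliased
disc (radius 12 px, intensity 0.55 below a 0.85 background, 1-px smoothed
rim — the typical brightfield appearance of a 3 µm bead) and a pipette tip
(two parallel dark bars ending at the tip; the anchor sits on the axis at
the tip), on sub-pixel trajectories, with i.i.d. Gaussian sensor noise
(SD 0.01 of full scale, about the shot-noise level of an 8-bit CCD at this
background), written as 8-bit multi-page TIFF.  Defocus events are
Gaussian blurs on listed frames (blur SD 2.5 px drives SD2 from ≈ 0.99 to
≈ 0.77, comfortably across the 0.95 threshold); an optional rectangle
occluder erases part of the bead rim.  Rendering is deterministic given
the seed.

Named presets mirror the canonical analysis situations: `basic` (456
frames at 65 fps, 0.1 µm/px — a clean single-interval run, bead pulled at
0.008 px/frame against a sinusoidally swaying pipette, Δx within the
linear regime), `interrupted` (one defocus episode, frames 120–160, after
which focus reverts so one pattern and one reference serve both flanking
intervals), `multiinterval` (a long middle stretch at a different stable
focus needing a locally cut pattern and offset alignment), `occlusion`
(> 50% of the rim hidden for 41 frames) and `separation` (the bead departs
mid-recording — the tracked Δx spike is faithful but physically
meaningless, the canonical caution case).

What the generator does **not** emulate: optical point-spread blur beyond
the 1-px rim, correlated/Poisson noise, illumination drift, debris,
out-of-plane bead motion, and the visible cell body.  Passing tests
therefore demonstrate correctness of the algorithms and their failure
semantics under controlled degradation, not performance bounds on any
particular microscope's footage; the sub-0.1 px precisions on these scenes
are best-case figures that real recordings (reported bead precision
30–50 nm) will not generally reach.

## Numerical choices and problem sizes

Running statistics use cumulative sums on mean-centred data (exact zeros
on constant input); per-frame SDs short-circuit constant frames.  The
Hough radius grid is integer; sub-pixel bead centres come from centroid
refinement only.  Degenerate inputs (flat patches, zero-variance
templates, empty candidate lists, constant series) return empty results or
flagged values — exceptions are reserved for caller errors (bad ranges,
invalid geometry, broken files).  Test and acceptance runs use the preset
scene sizes (456-frame reference scene, 200–400-frame event scenes at
200×120 px), which exercise every code path in seconds per scenario.
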