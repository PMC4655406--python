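# Methods

This note documents the models implemented in `neurotrace`, the numerical
choices behind them, what the synthetic phantoms do and do not emulate, and
the known limitations. Parameter names refer to `SomaParams`, `TraceParams`
and `QuantParams`.

## Image model and conventions

Images are single-channel rasters min–max normalized to `[ε, 1]` with
`ε = 1e-6`, so log-intensity is finite everywhere; a constant image maps to
all-`ε` with a warning. Stacks normalize globally (one min/max across all
slices) to preserve relative slice brightness. Normalization is idempotent
and exactly invariant under affine intensity changes `a·I + b` (`a > 0`, no
clipping), which is what makes traced geometry independent of exposure and
contrast settings. Coordinates are `(row, col[, depth])`, 0-based; angles
are degrees counterclockwise from the +x (column) axis with "north" =
decreasing row, in `(−180, 180]`. RGB inputs collapse by Rec. 601 luminance.

## Soma detection

* **LoG response** (`log_sigma_um`, default 7.5 μm): scale-normalized
  negated Laplacian of Gaussian, `−σ²∇²(G_σ * I)`. The LoG responds
  maximally to blobs of radius `σ√2`, so 7.5 μm targets the middle of the
  15–30 μm soma diameter range. The truncated discrete kernel's DC response
  is subtracted so a constant image yields exactly zero response. The scale
  is exposed because very large or small cell types would need retuning.
* **Response ratio threshold** (`response_ratio_threshold`, default 0.3):
  pixels with `response / max(response) ≥ t` form candidate soma regions.
  This single dial trades precision against recall (see the evaluation
  sweep below); 0.3 keeps somata of roughly one third the brightest soma's
  response.
* **Non-maximum suppression**: strict maxima of the response within a
  window of `2·⌈10 μm / pixel⌉ + 1` px (two somata closer than one soma
  radius merge), ties broken lexicographically by (row, col). The window
  comparison deliberately ignores the mask so that raising the threshold
  can only remove candidates — the candidate set is nested along the
  threshold sweep, which both guarantees the monotone precision/recall
  trade-off and lets the sweep reuse one detection pass.
* **Boundary refinement**: a two-phase piecewise-constant level set
  (morphological Chan–Vese) evolved from a 40-μm circle around the center,
  for at most `lsm_max_iter` sweeps (the morphological scheme moves the
  contour up to one pixel per sweep and is pixel-stable at convergence; the
  PDE formulation was rejected after it moved the contour far too slowly at
  any stable time step). Because the two-phase model happily follows bright
  neurites out of the soma, the segmented region is morphologically opened
  with a disk of radius 1.75 μm — by definition anything thinner than a
  neurite's 3.5 μm cannot be soma — before taking the component containing
  the center. A contour that collapses below 5 px² falls back to a 15-μm
  circle and is flagged.

## Neurite tracing

A trace is a sequence of points with fixed step `s1 = 15 px`, built from an
initial point on the 40-μm circle. Intensity along a candidate segment is
sampled every `arc_resolution_px = 0.5 px` (bilinear in 2-D, trilinear in
3-D; samples outside the image read `ε`), and the segment score is the sum
of log sampled intensities. The turn between consecutive steps is hard-
bounded by `max_turn_deg` (default 60°; 60° per 15-px step admits realistic
neurite curvature while excluding reversals). Headings are quantized at
`Δθ = arc_resolution/s1` rad (≈1.9°, 188 headings).

**Initial points** are angular local maxima of intensity on the 40-μm
circle, sampled at ≤0.5 px arc spacing and smoothed at neurite-width scale,
that exceed the circle median by `max(10⁻³, 4·MAD)`; maxima closer than 5°
merge keeping the brighter. The MAD margin suppresses noise maxima and
float-roundoff "maxima" on flat background.

**Scoring floor.** Path scores floor each sample at
`score_floor = 0.01` (the data keep the `ε` floor). Without this, one
background sample costs `|log ε| ≈ 13.8` — so much that near a neurite tip
the optimizer profitably bends the whole tail geometry sideways to delay
dark samples, producing zigzag endgames several pixels off the centerline.
Bounding the dark-sample penalty at `|log 0.01|` makes geometric fidelity
always cheaper than dark-sample avoidance.

### Chain model with dynamic programming (`trace_hmm`)

The turn constraint couples two consecutive steps, so the Markov state is
the pair (position, incoming heading); positions are quantized at
`arc_resolution` for state merging (states reached by permutations of the
same heading multiset merge exactly). The forward pass is an exact Viterbi
recursion; a beam (`beam_width = 500` states/step) keeps full-size images
tractable, and `beam_width=None` gives the exact DP used in the
enumeration-equivalence tests. The first step considers all headings, or
the outward half-plane when the soma is known; later steps may not re-enter
the soma's 40-μm circle (the bright soma interior is otherwise a
free-loitering region for the optimizer under noise).

**Termination** is sequential: after each step the current best path is
tested, and the first firing stops the trace. Two tests fire it:

1. the endpoint rule — endpoint intensity ≤ median of the surrounding
   10 × 10 μm window (side rounded to an odd pixel count, clipped at
   borders), inclusive, so a uniform image terminates immediately;
2. the step-contrast rule — the last step's score falls to or below
   `0.5 · n · q25(log window samples)`: the step's geometric-mean intensity
   no longer exceeds the geometric mean of the local background level and
   full scale. The background level is the lower quartile of log
   *interpolated* samples on a grid over the same window — lower quartile
   so the neurite occupying part of the window cannot contaminate it, and
   interpolated (not raw-pixel) statistics because on a zero-clipped noisy
   background raw pixel medians sit far below what the segment sampler ever
   reads. The rule exists because the endpoint rule alone is defeated by
   selection bias: the optimizer always steps onto the brightest of ~60
   candidate directions, whose endpoint is rarely below a median. The
   halfway-in-log-space level separates on-neurite from
   brightest-background steps by a wide margin in every background regime
   we generate (noiseless floor, zero-clipped noise, noise on a pedestal);
   its price is a detectability limit — neurites dimmer than the square
   root of the background level terminate.

After firing, the tip is localized by resampling the trailing two segments
at `arc_resolution` and cutting at the last lightly-smoothed sample still
above the midpoint between the trace's own ridge brightness and the local
background median; length accuracy then follows the arc resolution, not the
15-px step. The final partial step is the one place the fixed step-length
invariant is relaxed.

Sequential termination replaces "collect all terminated paths and take the
best": under log-likelihood scoring every step has non-positive score, so
comparing terminated paths of different lengths systematically prefers a
one-step bail-out into background over a long faithful trace.

### Fully-connected chain model with capped greedy search (`trace_fcm`)

Global optimization of a chain whose nodes all interact is intractable, so
the search is greedy with candidate sets: each candidate advances to the
best local maximum of the one-step score over its admissible heading fan;
when several local maxima exist (a branch point) the extras spawn new
candidates, capped at `max_candidates = 10` concurrent sets; spawning also
requires the extra direction to pass the step-contrast rule, so noise
wiggles do not consume the cap. Candidates terminate independently by the
same two rules. The returned candidate maximizes the **background-
referenced full-sequence score** `Σ_steps (segment score − n · log(local
median at the segment midpoint))`: every step brighter than its local
background contributes positively, so the maximizer favors the longest
consistently-bright branch — which is what distinguishes this tracer from
the chain model at junctions, where the DP's posterior always follows the
locally brighter branch regardless of length. The branch-trap phantom
(bright 40-μm branch vs dim 150-μm branch) is the discriminating fixture:
the chain model returns the short bright branch, the candidate-set search
the long one.

In 3-D the heading fan is a Fibonacci lattice of 700 unit vectors (~7.5°
spacing) restricted to the `max_turn_deg` cap, with local maxima judged
against each direction's six nearest lattice neighbours; depth is rescaled
by `microns_per_slice / microns_per_pixel` so steps and turns are
physically isotropic. A depth-1 stack reduces exactly to the 2-D tracer.

**Stacks without somata** are seeded at 3-D local intensity maxima
(26-neighbourhood) above the 95th intensity percentile, subsampled to ≤50
seeds with the `seed` parameter (the only randomness in the package), and
the per-seed traces are greedily linked: endpoint pairs within `2·s1` whose
terminal directions are compatible within the turn bound merge, closest
first, to fixpoint.

## Quantification

* `L* ` is the Euclidean distance from the tracing seed (on the 40-μm
  circle) to the nearest point of the soma boundary polygon
  (vertex-interpolated, via exact point-to-polygon distance); a seed inside
  the boundary gives `L* = 0` with a warning. Concentric circular somata of
  diameter d give exactly `(40 − d)/2` μm.
* Orientation is measured from the *sprouting point* — the boundary point
  nearest the seed (the paper-level concept names this point but does not
  construct it; nearest-point projection is the natural construction) — to
  the final traced point.
* Validation: sequences with total length < 20 μm are dropped; somata with
  no surviving sequence are rejected (this is what removes debris that
  fooled the blob detector); per soma the longest sequence is the axon and
  the rest dendrites, with path length as the default axon criterion
  (`axon_criterion="euclidean"` switches to straight-line seed-to-tip
  distance). Before labeling, sequences from one soma ending within
  `endpoint_dedup_um = 10 μm` of each other are collapsed to the shortest:
  adjacent initial points (e.g. a noise maximum beside the true crossing)
  otherwise produce two routes along the same neurite, and the
  longest-is-axon rule would prefer the inflated diagonal one.
* Evaluation: greedy one-to-one matching of detected to true centers within
  `match_radius_um = 10 μm`, closest pairs first; zero detections report
  precision 1.0 by convention. The threshold sweep runs detection once at
  the lowest threshold and reuses the nested candidate sets.

## Synthetic phantoms

Phantoms emulate the failure modes that motivate the pipeline: bright
elliptical somata (smooth plateau `exp(−ln2·ρ⁸)`, half-maximum exactly at
the stated radius), thin tubes along polylines with Gaussian cross-section
(`σ = width/2.355`, i.e. the stated width is the FWHM), per-segment
intensity steps, linear fade over the final `fade_tail_um` (exercising the
termination rule), side branches, debris blobs of soma-like size, broad
Gaussian halos, a constant background pedestal, and additive Gaussian noise
clipped to `[0, 1]` — all deterministic in a single seed. Ground truth
records the exact polyline, arc length, sprouting-to-tip orientation and
axon flag.

They do **not** emulate a PSF, photon (Poisson) noise, uneven illumination
within a field, textured backgrounds, or touching cells — so passing tests
demonstrate correctness of the geometry and the inference under the stated
noise model, not performance on any particular microscope's images.

Study conditions used by the tests and the acceptance script: recovery
phantoms are single straight neurites of 30–200 μm at 0.625 μm/px (a
200-μm neurite then fits a 768-px canvas with margin; the 0.3125 μm/px
example scale is used for the scale-conversion and L* checks), soma
diameter 20 μm, neurite intensity 1.0, either noiseless on a dark field or
noise σ = 0.1 on a 0.15 pedestal (real fluorescence backgrounds are
non-zero; a noiseless constant pedestal would be normalized back to the
floor anyway). The branch trap uses branches of 150 μm at intensity 0.7
and 40 μm at 1.0 splitting 20 μm from the soma boundary; the
precision/recall set uses ten randomized one-neuron phantoms with three
debris blobs each (6–12 μm, intensity 0.5–0.9, noise σ = 0.05 on a 0.1
pedestal).

## Numerical choices and edge cases

* Degenerate inputs: constant images normalize to the floor with a warning
  and terminate tracing at the seed; a seed with no admissible first step
  returns a single-point unterminated sequence; a level-set contour
  collapsing below 5 px² falls back to a flagged 15-μm circle; a
  degenerate orientation vector is NaN and flagged.
* Tie-breaking is deterministic everywhere: NMS plateaus keep the
  lexicographically first pixel; equal DP scores keep the lexicographically
  smallest endpoint; equal-length neurites rank by point count then
  endpoint.
* The chain-model quantification default in the pipeline is `fcm`: on
  unbranched neurites the two tracers agree to within one heading quantum,
  the greedy search is ~50× faster, and its tip localization is slightly
  more stable under noise; the DP tracer remains the reference for
  exactness (it is checked against exhaustive enumeration) and for the
  branch-behavior contrast.
* Reported problem sizes: recovery uses 20 phantoms per noise condition;
  DP-vs-enumeration uses 100 trellises of ≤4 steps × 7 headings; the sweep
  uses 10 phantoms × 9 thresholds.

## Known limitations

* Junctions are resolved only as "longest branch wins"; no tree is built
  (one SWC chain per traced neurite).
* Neurites dimmer than `√background` terminate early (the step-contrast
  rule's detectability limit).
* The chain-model tracer can overshoot by a step or two on very short
  (<40 μm) noisy neurites before the stopping rules fire; the candidate-set
  tracer does not share this failure mode, which is one reason it is the
  quantification default.
* A traced sequence attaches to the soma whose circle seeded it; a neurite
  passing near two somata is not re-assigned.
* Stack termination is less precise along depth because the axial window
  usually spans few slices.
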