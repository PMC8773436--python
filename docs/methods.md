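# Methods

This note documents the models, parameter choices, and numerical decisions
behind `fireflash`, and what the synthetic-data validation does and does not
demonstrate about real night-video recordings.

## Signal model

A firefly flash scene is modeled as a dark background (8-bit level ~10) with
additive Gaussian sensor noise (SD 3 by default) on which flashes appear as
compact bright footprints. A flash *signal* is either a single pulse
(*A. cerata*, *L. curtithorax*) or a burst of three closely spaced sub-pulses
treated as one signal (*L. kagiana*). Two timing characters summarize a
pattern:

* **FI** — time between the (first) peaks of successive signals of one
  individual. FIs are only ever computed within one individual's trace or
  track, never across individuals.
* **FD** — width of a signal where the intensity is 10% of the pulse height
  above baseline. For a multi-pulse signal, FD runs from the first pulse's
  10% onset to the last pulse's 10% offset; the start/end rule for bursts is
  an adopted convention (the reference measurements do not state one).

## Spot detection: topographic prominence

Per frame, spots are local intensity maxima accepted by prominence: peak
value minus the highest saddle connecting the peak to strictly higher
terrain must reach `prominence` (default 80 of 255), and the peak must reach
`min_background + prominence`. Semantics (8-connectivity):

* a plateau (maximal connected equal-valued set) is a maximum iff no
  neighbor is higher; accepted plateaus report their centroid rounded to the
  nearest pixel, ties toward the smaller index;
* equal-valued maxima connected above the saddle level count once (the
  plateau containing the raster-smallest pixel is reported), matching the
  one-marker-per-flooded-region behavior of interactive maxima finders;
* implementation: candidate maxima from a vectorized 3×3 maximum filter,
  then an exact flood test per candidate — the connected component of
  `{pixels > value − prominence}` must contain nothing higher. The test
  suite checks exact equivalence against an independent brute-force saddle
  search on random grids.

`min_background` (default 10) is a floor against noise maxima on dark
scenes; the reference workflow names only the prominence setting, so the
floor is an implementation choice, exposed in configuration.

Clip-level detection decimates the stack first (default one frame in 30) so
a flash lasting several frames is counted once — the reference workflow's
sole duplicate control. For analyses that need *every* flash localized once
(per-pair displacement measurements), detection instead runs on every frame
with the optional duplicate merge: spots in consecutive retained frames
within `merge_radius_px` chain into one flash, keeping the brightest. The
merge radius (8 px in the scene analyses here) must exceed the within-flash
drift per frame (~2 px at the default flight speed and 30 fps) and stay far
below the between-flash displacement (~59 px).

## Track linking and behavior classification

Spots are linked greedily in time: each spot joins the nearest track whose
last spot lies within `max_gap` seconds (default 6, above the longest
perching FI of ~4.8 s) and within the track's distance gate; otherwise it
starts a new track. The gate is adaptive: an established track accepts up to
2.5× its median step, floored at 30 px and capped at `max_link_distance`
(default 160 px, above the simulator's maximum flying step). The adaptive
gate exists because the two behavioral regimes differ by ~6× in step scale;
with a single fixed gate a stationary flash cluster readily captures a
passing flyer's flashes (closed-loop behavior accuracy dropped to
0.6–0.9), while per-track gates keep clusters tight and trajectories
coherent (≥0.9). Greedy linking remains order-dependent and can swap
identities when trajectories cross; the reference workflow resolved
crossings manually, and no claim is made here beyond the sparse scenes
tested.

A track is classified from its mean consecutive flash-to-flash distance,
with footprint elongation (major/minor axis of the half-height region) as a
secondary cue:

* flying: mean distance > 25 px, or within the gray zone [15, 25] px with
  mean elongation ≥ 1.5;
* perching: mean distance ≤ 25 px and mean elongation < 1.5;
* otherwise (including tracks with < 3 spots): ambiguous.

The 25 px threshold sits between the published group statistics (59.2 ± 27.4
px flying vs 11.1 ± 5.5 px perching — roughly flying mean − 1 SD and
perching mean + 2.5 SD); it is resolution- and range-dependent and therefore
configurable. The gray-zone span (0.6× the threshold) is an implementation
convention.

## Pulse timing

ROI traces are per-frame mean intensities (static rectangle, or a window
following a track's interpolated positions). Baseline defaults to the trace
median — appropriate when flashes occupy a minority of samples; a
lower-quartile-mean alternative exists for high duty-cycle traces. Pulse
peaks are sample-level local maxima more than `min_height` (default 5
intensity units, a flicker rejection floor) above baseline; 10% crossings
are linearly interpolated between samples and searched outward to the
adjacent valleys, splitting overlapping supports at the valley. Linear
interpolation is what resolves FD ≈ 0.1–0.2 s to better than one frame at
30 fps; its residual bias on the raised-cosine test pulses is ≈ +5 ms per
pulse at 30 Hz sampling and ≈ +2 ms at 60 Hz, well inside the validation
tolerances.

Grouping merges successive pulses whose peak-to-peak gap is strictly below
`gap_threshold` into one signal. The default 0.25 s sits between the
within-burst spacing of the triple-pulse species (~0.08 s) and its shortest
between-signal FI (0.42 s). For single-pulse species the pipeline disables
grouping (threshold 0), since *L. curtithorax* FIs reach 0.07 s — below any
safe gap.

## Species matching

Reference ranges are closed intervals (a range printed as "0.6–1.2 s" is
taken endpoint-inclusive). `summarize` reports order statistics with a
`coverage` parameter: the default 0.90 returns the 5th–95th percentile span
(one reading of a "Min–Max covering 90% of points" summary); `coverage=1.0`
returns literal extremes. Classification never depends on re-estimated
ranges: the published endpoints ship verbatim as the default references.

The matching rule is applied literally: assignment requires exactly one
species above the 50% fraction with all others at or below 50%; two species
above 50% yields "unmatched" (the ≤50% clause fails). Individuals without 7
flash events inside any 10 s window are "excluded" and tallied separately,
outside the composition denominator. Display percentages round to integers;
raw fractions are retained in outputs.

`compare_groups` is Welch's unequal-variance two-sample *t*-test (two-sided),
delegated to `scipy.stats.ttest_ind`; the all-constant equal-mean degenerate
case returns (0, 1) by convention.

## Spectra

Emission spectra (400–700 nm readings) are averaged pointwise after linear
resampling onto the first reading's grid. The half-maximum level is measured
above the series minimum (the dark offset; the reference readings state no
baseline handling), with linearly interpolated crossings. λmax is refined
below the 1 nm grid by a least-squares parabola over the contiguous top-10%
region of the peak — exact for symmetric peaks and robust to noise, unlike a
three-point parabola whose curvature estimate is noise-dominated on smooth
spectra; when the top region is too narrow the three-point formula (vertex
clamped to ±0.5 grid steps) is the fallback. A missing half-maximum crossing
raises a boundary error carrying the partial summary.

## The simulator

The generator's role is to produce scenes and traces whose *measured*
statistics equal the published per-species values, with exact ground truth.

**Timing.** FI and FD draw from truncated normals bounded by the species'
Min–Max range. The parent location is moment-matched (solved numerically) so
the truncated distribution's mean equals the published mean; using the
published mean directly as the parent location would shift the emitted mean
wherever the window is asymmetric (e.g. *L. curtithorax* FI would emit 0.228
s instead of 0.20 s). The parent scale is the published SD; on narrow
windows the realized SD is necessarily smaller (no distribution on a width-w
interval truncated from a unimodal normal exceeds the uniform's w/√12), so
the simulator reproduces means exactly and SDs only as far as truncation
allows.

**Pulses.** Each pulse is a raised cosine whose 10%-height width equals the
drawn FD (width = 0.795 × the support), so zero-noise traces close the loop
to within one sample. Triple bursts place three sub-pulses
`intra_triple_gap` apart (default 0.08 s — a free parameter: it must stay
below the grouping threshold and small against the 0.42–0.53 s FI; the
reference figures show tight triples but print no spacing). Consequently a
simulated triple signal spans 2×gap + sub-pulse width ≈ 0.22 s, wider than
the published *L. kagiana* FD range (0.07–0.15 s) — those two published
numbers are mutually inconsistent with any resolvable burst, and FI, the
quantity validated here, is unaffected. A configuration error is raised when
the sampling rate leaves fewer than 3 sample instants on the narrowest pulse
(support × rate + 1 < 3).

**Scenes.** Flying individuals move between flash-to-flash waypoints whose
step lengths draw from a moment-matched truncated normal (defaults 59.2 ±
27.4 px on [5, 150]); positions advance through each flash at the implied
velocity and sub-frame substepping integrates the footprint along the path,
yielding the oblong motion-blurred shape. Each individual keeps to its own
home region (a cell of a shuffled partition of the frame), emulating
patrolling flight; steering preserves step lengths exactly by re-drawing the
direction. Perching individuals jitter about a fixed anchor with per-axis SD
6.3 px, which makes the mean distance between successive flash positions
(Rayleigh with σ√2) ≈ 11 px, and render round footprints. All randomness
flows from one seed through SeedSequence spawning: identical specifications
render bit-identical frames.

**Case-study populations** regenerate the 78 flying individuals of the
reference survey: 56 with 7–21 FI points each from the *A. cerata* profile,
10 from *L. kagiana*, and 12 "irregular" individuals drawing uniformly on
0.13–2.03 s (the span observed in that group).

**What passing does and does not show.** The simulator covers flash timing,
trajectory/cluster geometry, footprint shape, dark Gaussian noise, and
sparse co-occurrence. It does not emulate vegetation occlusion, camera
shake, non-Gaussian sensor noise, brightness variation with distance and
angle, or crossing trajectories at realistic densities — so closed-loop
accuracy bounds what the algorithms can do under the published statistics,
not field performance.

## Validation problem sizes

The reproduction script pools enough draws that Monte-Carlo error stays well
inside each comparison tolerance: ~320 intervals (10 simulated individuals)
for flying *A. cerata* FI, ~270/~450 for the other two species, ~330 pulses
for FD, ~480 intervals (11 individuals, 110 s traces) for perching FI, and
12 replicate scenes (3 flyers × 7 flashes each, ~210 pairs) for the
flight-displacement recovery — a single 18-pair scene would leave the drawn
sample mean itself with ~6 px standard error, swamping the quantity under
test. The 78-individual case study uses the published group sizes as-is.

## Known limitations

* Greedy linking has no global assignment step; dense or crossing
  trajectories can swap identities.
* MP4/MTS reading requires an imageio codec backend; TIFF stacks are the
  tested path.
* FD for triple bursts follows the adopted first-start-to-last-end rule.
* Constant frame rate is assumed (timestamps are t0 + index × delay);
  variable-rate containers are not supported.
* The matching rule is the literal >50%/≤50% interval rule — no
  likelihood-based classification.
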