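# Methods

## Signal model and processing chain

A session is an ordered set of imaging episodes recorded back-to-back at a
fixed frame rate; the default protocol is seven 40-s episodes at 5 Hz
(200 frames) with an 8-s (40-frame) baseline, in the order puff, skin
brush, pinch, colon-brush insert, colon-brush extract, balloon insert,
balloon inflate. The first three stimuli are external (perineal skin), the
last four internal (colonic). The acquisition pauses between episodes are
represented as boundary indices, never as recorded frames; heatmaps draw
white gap lines at those boundaries.

Stimulus timing within an episode is not part of the acquisition record, so
the onset is placed by convention at the first post-baseline frame
(frame 40 by default) and the response window is the full half-open
interval [onset, episode end). This is the most permissive window
consistent with "response follows the stimulus"; a narrower window would
only lower measured peaks.

Processing order is: raw mean-over-footprint traces → annulus subtraction →
per-episode percent ΔF/F → responder calling. Whether donut subtraction
precedes or follows normalization is an open choice in this kind of
pipeline; subtracting first makes the correction exact in raw-intensity
units (a uniform additive background cancels identically, which the tests
exploit) and keeps ΔF/F scale-invariant.

### Annulus geometry

Each cell's annulus is its footprint dilated by `gap + width` minus the
footprint dilated by `gap`, with **all** labeled pixels removed so a
neighbouring cell inside the donut radius never leaks into the correction.
Defaults: gap 1 px, width 3 px on a 256×256 field with radius-4 footprints.
These are conventional values, config-exposed; the subtraction uses scale
1.0 (direct subtraction), with a `neuropil_scale` parameter for fractional
correction. An annulus left empty by crowding or the image edge is a
per-cell error with a remediation hint, not a silent zero.

### Baselines and ΔF/F

F₀ is re-estimated per episode as the mean over that episode's baseline
frames; ΔF/F = 100·(F−F₀)/F₀ in percent. A non-positive F₀ raises an error
listing the affected (cell, episode) pairs — such cells must be excluded
explicitly rather than silently zeroed. Per-episode baselines are the only
reading consistent with concatenated display of episodes recorded with
pauses in between.

## Responder calling and classification

The activation threshold is **strictly** ΔF/F > 5% on the per-episode peak;
a peak of exactly 5.0% is not a response. Exclusion rules, in precedence
order when several fire (structural defects first):

- **Overlap**: the footprint shares ≥ 1 pixel with another ROI, detected
  from the ROI construction record (a flat label image cannot represent
  overlap, so `RoiSet` keeps per-cell footprints when available).
- **Spontaneous**: ΔF/F above threshold for ≥ 3 consecutive frames (0.6 s
  at 5 Hz) inside any episode's baseline window.
- **Persistent**: after the onset of the first responding episode, ΔF/F
  stays above threshold in ≥ 80% of the remaining session frames
  ("remained active for the rest of the experiment").

The 3-frame run and 80% fraction quantify otherwise qualitative rules and
are config parameters. Then cells responding to ≥ 1 internal and ≥ 1
external episode are excluded as both-site artifacts; internal-only
responders are Internal; any puff/skin-brush responder is External gentle
(a pinch co-response does not demote it); pinch-only responders are
External noxious. Included responders are pooled to 100%; excluded cells
and non-responders enter neither numerator nor denominator.

Group comparison is a Pearson chi-square without continuity correction on
the 2-group × 3-category count table, dof = (rows−1)(cols−1) = 2; a category
empty in both groups is dropped with a warning and the dof reduced. The
implementation is `scipy.stats.chi2_contingency`; the test suite checks it
against a hand-written Σ(O−E)²/E loop. Identical count vectors short-circuit
to χ²=0, p=1 exactly.

A note on monotonicity: the per-episode responder calls and the number of
cells with ≥ 1 responding episode are non-increasing in the threshold, and
the tests assert this. The *included*-responder total is **not** monotone in
general: raising the threshold can push a both-site cell's weaker response
below threshold, converting it from excluded to an included single-site
responder. The suite asserts the properties that actually hold.

A blinded-equivalence harness (`blinded_proportions`) shuffles and
de-identifies the trace matrix before classification and must reproduce the
labeled proportions exactly, mirroring a blinded-vs-unblinded analyst check.

## Activity maps and heatmaps

SD maps use the population standard deviation (ddof = 0) per pixel over all
frames of all episodes of the requested site, pooled by default with a
single-episode option. Heatmap blocks are ordered Internal, External
gentle, External noxious; within a block rows descend by session-peak ΔF/F
with ties broken by ascending cell id — a deterministic replacement for
what is manual sorting in practice.

## Quantification ratios

- Gastric emptying: the direction of "percentage of total signal" is
  ambiguous, so emptying is defined as the non-stomach share,
  100·rest/(stomach+rest), and retention is co-reported; the two sum to 100
  to 1e-12.
- Stool water content: 100·(wet−dry)/wet — the standard moisture-content
  convention with the wet weight as denominator.
- Nerve density: nerve-mask pixel count / field area (masks are consumed
  pre-segmented; an Otsu helper exists for synthetic images only).
- IGVE density: innervated-ganglia count / field area, reported per px² and
  per 1000 px².

## The synthetic-data generator

The generator is the package's study-condition definition, not a test
fixture. Defaults: a 256×256 field with 34 radius-4 disk cells
(10 internal-only, 8 external-gentle, 4 external-noxious-only, 3 both-site,
5 silent, 2 spontaneous, 2 persistent — inside the 10–50 neurons-per-animal
range of such recordings), baseline brightness drawn uniformly in 80–120
intensity units, background level 100 with a 5-unit sinusoidal drift
(period 20 s) and Gaussian sensor noise of sd 1 (1% of background), clipped
at zero. Transient amplitudes are drawn per class — 10–60% ΔF/F for
skin-evoked classes, 10–30% for colonic ones, matching the observed spread
of responses — or pinned to a single value via `amplitude_pct`.

The transient kernel is a step rise at stimulus onset with exponential
decay (τ = 1 s, GCaMP6f-like); any kernel whose peak equals the planted
amplitude would serve, and τ is a parameter. With zero noise and drift, the
rendered peak percent change over baseline inside a responding footprint
equals the planted amplitude to 1e-6 relative (the tiny departure is the
previous episode's decay tail, ~e⁻³² of the amplitude).

Spontaneous cells fire one transient at baseline frame 5 of the first
episode. Persistent cells are rendered as a **non-decaying staircase**: a
unit step at their first responding onset (the pinch episode) and a fresh
step at every later episode onset. A flat elevation would be invisible to
per-episode ΔF/F (the elevated baseline renormalizes it away), so the
staircase is the simplest signal that keeps every subsequent episode's
ΔF/F above threshold and makes the persistence rule recoverable; with the
default amplitude range the fraction of post-first-response frames above
threshold is ≈ 83%, comfortably over the 80% rule.

The background is spatially uniform by design so that annulus subtraction
is provably exact and testable to 1e-9; a `halo_sigma_px` option smears
cell signal into the surround for studying local contamination, off by
default. What the generator does **not** emulate: optics/PSF, motion
(movies are born registered; real movies need prior registration),
photobleaching, Poisson photon statistics, vascular artifacts, correlated
neuropil. Passing tests therefore demonstrate correctness of the analysis
arithmetic and decision rules under the stated signal model, not robustness
to those real-data effects.

All generators are bit-reproducible for a fixed seed
(`numpy.random.default_rng`); cell placement is rejection sampling with a
minimum center distance of 2r+2 so unplanted footprints never touch, and an
optional deliberately overlapping pair exercises the overlap exclusion.

## Numerical and engineering choices

- Rendering and analysis use float64 end to end; the annulus-exactness and
  oracle-equivalence checks are at 1e-9 absolute.
- Coordinates are row-major (row, col), 0-based; frame intervals are
  half-open [onset, n_frames).
- The pipeline writes a deterministic report bundle (CSV/JSON/TIFF/PNG) and
  a manifest (config SHA-256, package versions, seed, per-stage counts);
  two runs with one seed are bit-identical, which the suite verifies by
  hashing every bundle file. The full simulated movie is written only on
  request (`save_movie`) to keep bundles small.
- Oracle checks (trace extraction, annulus correction, SD maps, chi-square)
  run against brute-force loop implementations on small instances; problem
  sizes in the test suite (48×48 or 96×96 fields, short 3-episode schedules
  where geometry allows, the full default session where the condition
  demands it, 20 seeds for the noisy-recovery study) were chosen as the
  smallest instances that still exercise every rule.

## Known limitations

- Responses to different puff durations (0.2–5 s) and balloon pressures
  (100–200 mmHg) are pooled into their episode's call; intensity labels are
  carried as metadata only.
- ROI segmentation is out of scope: footprints are inputs, as in practice
  where they are drawn by hand.
- The both-site exclusion makes the included-responder pool non-monotone in
  the threshold (see above); comparisons across thresholds should use the
  per-episode calls.
- The chi-square is the pipeline's terminal statistic; behavioral-assay
  inference beyond the defined ratios is out of scope.
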