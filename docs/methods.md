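# Methods

`isletwave` analyses intravital Ca²⁺ recordings of pancreatic islets — per-cell
GCaMP fluorescence traces acquired at 3 frames/s over 400-frame captures
(≈133 s) — and ships a ground-truthed synthetic-recording generator so every
stage of the analysis can be validated without animal data. This note records
the models, the tunable parameters that matter, the numerical conventions, and
the design choices made where the underlying analysis left them open.

## Activity taxonomy and its operationalisation

Captures are categorised on a five-level scale:

| level | name | meaning |
|---|---|---|
| 0 | no activity | no detected Ca²⁺ onsets |
| 1 | oscillations | Ca²⁺ rises at one or more sites that do not advance across the islet |
| 2 | partial wave | a wavefront with a defined origin that covers only part of the islet |
| 3 | wave | a wavefront spreading across the whole islet |
| 4 | superwave | a recurrent (≥ 2) whole-islet wave within one capture |

The islet is split into three ordered regions (distal / middle / proximal)
along an axis; these are the three regions whose mean-intensity traces are
conventionally plotted to illustrate propagation. Because an isotropic cell
cloud has no preferred principal direction relative to an incoming wave, the
classifier re-fits the axis per event from the onset-time gradient (least
squares of onset on position), falling back to the principal axis of the cell
positions when no onsets define one. Regions are equal-count bands (±1 cell)
along the axis, ordered distal→proximal; hand-drawn region assignments can be
supplied instead via an explicit axis vector.

**Event detection.** Traces are smoothed (below), converted to ΔF/F₀
(F₀ = per-cell lower decile), and thresholded at median + `k_sd`·σ with
`k_sd = 4`. σ is the baseline noise SD. Estimating σ from the smoothed trace
itself is unreliable — a window-`w` rolling average leaves only ≈ n/w
independent samples — so when the pre-smoothing trace is available (the
pipeline always passes it) σ is estimated robustly from its first differences
(MAD/√2) and scaled by 1/√w̃(t), where w̃(t) is the effective (truncated)
window length at frame t; the threshold therefore rises near the capture
edges, where smoothing attenuates noise less. Above-threshold runs shorter
than 2 frames are dropped, runs closer than 2 s merge, and each event's onset
is the linearly interpolated crossing of half the event peak before the peak.
On noiseless transients this lands within one frame of the analytic half-max
time of the kernel.

**Event classification.** Onsets are clustered in time (a gap larger than the
propagation window, 2·diameter/v_min with v_min = 10 µm/s, starts a new
event). An event is an ordered wave when

1. it recruits ≥ 4 cells,
2. its onset span exceeds one frame (a synchronous whole-islet burst with
   sub-frame lag is an oscillation, by convention) but is at most
   diameter/v_min — a wavefront crosses the islet in ≈ diameter/velocity
   seconds, whereas unordered activity clustered into one event spreads over
   much of the capture,
3. the Spearman correlation between cell onset times and positions projected
   on the event axis is ≥ 0.4.

Criterion 2 carries most of the discrimination between oscillations and
waves; 0.4 in criterion 3 tolerates the onset jitter that rank correlations
inherit from half-max detection on noisy traces while still rejecting the
residual unordered clusters. A wave is **full** when all three regions are
recruited (each with ≥ 50% of its cells; alternatively a single cell-level
criterion, e.g. ≥ 90% of all cells, via `full_fraction`), otherwise
**partial** — note that a partial wave may sit inside a single region: with
the default recruitment extent (40% of the islet diameter) it recruits about
one band's worth of cells, so counting ≥ 2 recruited regions would
mislabel most partial waves as oscillations. The capture's level is 4 with
≥ 2 full waves, 3 with one, 2 with any partial wave, 1 with any remaining
activity, 0 otherwise; ties break toward the higher level.

**Wavefront velocity** is v = d/Δt in µm/s. The default reference points are
the first- and last-recruited cells of the event (d = their Euclidean
distance, Δt = their onset lag): for radial propagation from an origin that
is itself a cell this estimator is consistent, and the constant detection lag
of half-max crossings cancels in Δt. A region-based variant
(`method="centroids"`: d between the centroids of the first- and
last-recruited regions' cells, Δt between their median onset times) is
provided; for radial waves the centroid chord underestimates the path-length
difference and can bias v by ~20–30%, which is why it is not the default.

## Smoothing

The noise-reduction function is a centred moving average whose window is 5%
of the data points: w = round(0.05·n), incremented to the next odd integer
(400 frames → 21). Edges use the truncated, shrinking window, so output
length equals input length and constants are fixed points; the interior
impulse response peak is A/w. Smoothing precedes both onset detection and
correlation analysis.

## Connectivity

Pairwise Pearson R is computed between all smoothed cell-trace pairs over a
100-consecutive-frame window (~30 s; the window start is explicit and
logged), excluding the autocorrelation diagonal. Zero-variance traces give
flagged-undefined entries, excluded from every numerator and denominator.

"Significantly connected" has two modes:

- **permutation** (default): the null for each pair is the correlation of one
  trace against circular shifts of the other, preserving each trace's
  autocorrelation. All lags are computed at once by FFT cross-correlation;
  when `n_shuffles` ≥ window−1 (the default 1000 is) every distinct nonzero
  lag is used exactly once, so p = (1 + #{null ≥ observed})/window is
  rank-exact, the test's type-I error is exactly ⌊α·window⌋/window under lag
  exchangeability, and the result is deterministic without a seed. A pair is
  connected when p ≤ α (0.05) and R > 0 (one-sided, positive).
- **threshold**: R ≥ 0.25 by default, matching analyses that draw
  connections from a fixed-R scale upward.

No multiple-testing correction is applied by default; Benjamini–Hochberg can
be layered on by the caller from the returned p-values. Summaries: % of
defined pairs significant, % of cells with ≥ 1 significant partner, and the
mean of strictly positive off-diagonal R (undefined — flagged `None` — when
no positive R exists). Drawn connections use the standard colour scale: blue
R 0.1–0.25, green 0.26–0.5, yellow 0.51–0.75, red 0.76–1.0, with bins closed
on those printed endpoints and continued half-open between them (0.255 →
green); R < 0.1 and negative R are not drawn. Cells with the maximum
significant degree (> 0) are hub dots.

Longitudinal metrics are baseline-corrected per islet as fold-change over the
week-0 value; a missing, undefined or zero baseline flags the islet as
excluded rather than propagating silently.

## Synthetic generator

The generator emulates the study conditions: 18–40 cell-scale ROIs per islet
(positions sampled uniformly in a 60 µm-radius disc with ≥ 12 µm spacing,
matching 10–20 µm ROI diameters, by bounded rejection sampling with an
area-bound infeasibility check), 400-frame captures at 3 frames/s, and the
five activity regimes. Transients use a single-compartment kernel
A·(1−e^(−t/rise))·e^(−t/decay) with rise 0.3 s and decay 2.0 s — GCaMP-like
kinetics with only two parameters. Level-1 onsets are independent per-cell
Poisson times (mean 2 events/capture) with no spatial ordering; levels 2–4
propagate radially from a peripheral cell at `wave_velocity` (cohort default
40 µm/s — the analysis treats wave speed as tens of µm/s; no measured value
is available, so this is a convention, as are the kinetics and noise
magnitudes), with onset(cell) = start + distance/velocity. Level 2 recruits
cells within 40% of the islet diameter of the origin; level 4 repeats the
full wave (same origin) at evenly spaced starts. Noise is additive Gaussian
per frame (SD 0.05 relative to unit amplitude and unit baseline in the
default, "low-noise" condition), with optional Poisson photon noise.
Rendering to image stacks places an isotropic Gaussian spot per cell
(σ = spot diameter/4) with per-frame amplitude equal to the trace, quantised
to 16-bit at 1000 counts/unit so written TIFFs round-trip exactly.

The default cohort design mirrors the study's direction, not its exact
per-week counts (which are published only graphically): sham islets start at
wave-dominated distributions and collapse to 80% inactive by week 10, while
VSG islets reach 100% wave/superwave by week 8 and keep it; 20 islets per
group, weeks 0/4/8/10, islet geometry persisting across weeks, all per-islet
seeds derived from one master seed.

What the generator does *not* emulate: photobleaching, eye-motion artifacts,
vascular occlusion, non-circular islet geometry, glucose dependence, or any
electrophysiological coupling mechanism. Passing tests therefore demonstrate
that the analysis recovers the constructs it defines (levels, velocities,
correlation structure) under idealised acquisition statistics — not that it
is robust to every artifact of real intravital imaging.

## Numerical conventions and degenerate inputs

- Timestamps are frame_index/fps, 0-based; 100 frames at 3 frames/s is
  treated as 33.3 s where seconds are derived (printed "30 s" labels are
  kept as labels, frames being definitive).
- Coordinates: µm relative to the islet centroid; the centroid maps to the
  image centre at a given pixel size; pixel centres sit at integer 0-based
  coordinates.
- Pearson values are clipped to [−1, 1] against round-off; identical traces
  give exactly 1.0.
- Partition axis sign: positive skew of the projections, ties broken so the
  largest-magnitude projection is positive — making the partition invariant
  under rigid rotation when the axis is recomputed.
- Degenerate inputs raise typed errors (`PackingInfeasibleError`,
  `OutOfBoundsError`, `UndefinedVelocityError` for Δt ≤ 0, `NotAWaveError`,
  `BaselineUndefinedError`, `FormatError`) rather than returning silent
  zeros; an all-constant trace simply has no events.
- The two-group comparison is the two-sided unpaired Student's t-test;
  identical samples return t = 0, p = 1, and zero pooled variance with
  unequal means is flagged with p → 0. Two-way ANOVA with multiplicity
  adjustment is out of scope.

## Problem sizes used in validation

Validation runs are sized to be decisive yet quick: classification recovery
uses 200 recordings (40 per level, noise SD 0.05, velocities 20–60 µm/s);
velocity recovery uses noiseless full waves at 20/50/100 µm/s (8 islets
each); permutation calibration uses 500 replicates of 20 independent noise
cells (95 000 pair tests); the longitudinal direction check runs the full
default cohort (160 captures) under 100 master seeds.

## Known limitations

- At 3 frames/s a partial wave faster than ~100 µm/s crosses its ~50 µm
  extent in under one frame and is indistinguishable from a synchronous
  burst; such events classify as oscillations (the velocity analysis is
  restricted to full waves, whose span is resolvable at all tested speeds).
- The five-level scale assigns one category per capture (the maximum
  supported by its events); mixed regimes within one capture are not
  represented.
- Rare noise excursions (≈0.2% of cells per capture at k_sd = 4) can lift a
  truly inactive islet to level 1; this is the dominant residual
  classification error.
- The permutation null assumes circular stationarity within the window;
  edge effects of the truncated smoothing window make it slightly
  approximate on smoothed traces (it is exact on raw traces).
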