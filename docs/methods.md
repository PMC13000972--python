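# Methods

This note documents the models, conventions and numerical choices behind
`windfleck`, in the spirit of a model-description appendix: what each
stage assumes, which knobs matter, and what the synthetic-data generators
do and do not emulate.

## Quantity of motion (QOM)

For consecutive RGB frames (channel values in [0, 1]) and a pixel zone,
the per-pixel absolute channel difference |Δ| is aggregated within the
zone and summed over the three channels.  Three aggregations are
available:

- `mean_square` (default): mean of |Δ|² per channel.  This is an
  *uncentered* second moment.  It satisfies both anchor values — 0 for
  identical frames and 3 for a uniform white↔black flip — whereas a
  centered within-zone variance of |Δ| is 0 for *any* spatially uniform
  change and bounded by 0.75 per channel, so it cannot reach 3.  The
  uncentered moment is therefore the default; `centered_variance` and
  `mean_abs` remain selectable.
- QOM sample timestamps are placed at the midpoint of each frame pair
  (the difference is a property of the interval, not of either frame).
- Pixel coordinates are 0-based, row-major, origin top-left; zone
  membership is pixel-center-in-polygon (shapely).  The plot polygon's
  bounding box is divided into a 16×9 cell grid; a user-supplied 9×16
  integer map groups cells into analysis zones (the mapping of cells to
  zones is scene metadata and cannot be derived from first principles; a
  simple column-pair default exists for synthetic scenes).
- Reference correction subtracts the mean QOM of the static reference
  zones elementwise and floors the result at 0 by default: downstream
  class binning is logarithmic (e⁻¹¹ lower edge), so non-positive values
  are excluded from class assignment either way, and flooring keeps the
  corrected series interpretable as a magnitude.
- Video stabilization is out of scope; frames are assumed pre-stabilized.
  The statistic cannot distinguish kinds of movement (sway vs. flutter),
  only its magnitude.

## Windfleck detection

The PPFD series (100 s⁻¹, uniform; records with gaps larger than two
sample intervals are split and processed per segment) is reduced to an
alternating sequence of minima and maxima:

- Runs of equal consecutive values are compressed.  `find_turning_points`
  reports interior sign changes of the first difference, with a plateau
  contributing a single turning point at the *first* index of its run.
- For event extraction the series endpoints (or their flat runs) also act
  as extrema, and flat runs adjacent to an event use rise-onset/fall-offset
  conventions: an event *starts* at the last sample of the flat run before
  its rise and *ends* at the first sample of the flat run after its fall.
  With these conventions a triangular pulse of base `w` on a flat baseline
  has duration exactly `w` — the natural reading of "duration" for a pulse.
- Pruning: an adjacent extremum pair fails if its amplitude is below the
  absolute threshold (default 5 µmol m⁻² s⁻¹) **or** below the relative
  threshold (default 5 %) times the lower of the two values (the local
  baseline).  Failing pairs are removed smallest-amplitude-first (ties:
  earliest position), each removal merging its neighbours; this repeats to
  convergence, making the result independent of scan order.  A retained
  event therefore passes *both* thresholds.  The implementation uses a
  lazily invalidated heap over a doubly linked extrema list; the test
  suite checks it event-for-event against a naive rescan oracle.
- Intensity = peak − baseline where baseline is the PPFD at the start
  turning point.  Integrated increase = trapezoidal integral of the trace
  minus the integral of the start–end chord, clipped at 0 (a
  concave-interior event could otherwise be negative).
- Summary: frequency = events / record length (also reported per 100 s);
  mean time between flecks = mean of (next start − previous end),
  undefined (NaN) for fewer than two events.
- Spectral input is converted as PPFD = 10⁶ ∫₄₀₀⁷⁰⁰ E(λ) λ/(h c N_A) dλ
  (trapezoid on the native grid, endpoints interpolated onto 400/700 nm).

## Synchronization

All streams are brought to the 100 s⁻¹ PPFD clock: QOM by linear
interpolation, wind by step extension (each 1 s value repeated 100×,
stamped from its interval start).  Cross-correlations are
Pearson-normalized per lag on the overlapping window — the
"largest absolute cross-correlation" zone criterion is then scale-free — over
a symmetric integer-lag grid (default ±500 samples = ±5 s, covering
manual-start offsets; automatically narrowed for records too short to
support it).  Positive lag means the second series is delayed relative to
the first.  Lags are integer samples (0.01 s); no sub-sample refinement,
since fleck durations of interest are ≥ 0.05 s.

Zone choice: proximity to the light diffuser (and sun angle) is scene
metadata, so the caller passes the near-diffuser candidate zones; among
them the zone with the largest |PPFD–QOM| correlation wins, ties to the
lowest id.  The wind shift is the lag maximizing the product of the
PPFD–wind and QOM–wind correlations over lags where the QOM–wind
correlation is positive (negative values would mean more wind produces
less motion); if no lag qualifies the estimator reports failure rather
than a value.  The pipeline applies the estimated shift to wind and
shifts QOM by the PPFD–QOM argmax, recording both in the run-report.
A canopy response lag folds additively into the estimated shift — the
estimator recovers the total offset between records, which is what
alignment needs.

## Binning and cultivar indices

Wind classes are half-open intervals of 0.3 m s⁻¹ from 0; QOM classes are
the 15 half-open intervals between the 16 edges exp(linspace(−11, −2, 16))
(constant ratio between consecutive edges), which roughly equilibrates
observation counts on the log scale.  Values outside the edges — including
QOM exactly 0 after reference flooring — are "outside" and carry no class.
Each windfleck is assigned the *mean* synchronized QOM (and wind) over its
[start, end] window, which is robust to 0.01 s jitter; because a mean can
fall in a class no single sample occupies, the pipeline reports such
classes as missing.  Per-class frequency = events / time-in-class, with
classes holding fewer than two events reported as missing.  Cultivar
indices (motion sensitivity = mean QOM / mean wind; light modulation
efficiency = fleck frequency / mean QOM) are z-scaled across the panel
with sample SD; a zero-spread axis reports 0 for every cultivar rather
than failing.

## Variance decomposition and heritability

Inputs are variety × block tables; technical replicates are averaged to
cell means first.  The residual component σ̂²_r is the pooled sample
variance of cell means about their variety mean; the block component is
the variance of block means minus σ̂²_r/n_varieties (floored at 0); and
the variety component is, by default, the ANOVA method-of-moments
estimator σ̂²_V = var(variety means) − σ̂²_r/n_blocks.  Broad-sense
heritability is H² = σ̂²_V / (σ̂²_V + σ̂²_r/n_blocks), clipped to [0, 1];
repeatability is σ̂²_block over the total.

Two estimator subtleties are deliberate:

- `correct_bias=False` reproduces the literal plug of the heritability
  formula with the raw variance of variety means.  That raw variance has
  expectation σ²_V + σ²_r/n, so the literal plug is upward-biased —
  severely so when σ²_V is small (a true H² of 0.2 reads as ≈ 0.5 for a
  10-variety × 3-block panel).  The corrected estimator is the default.
- Even with unbiased components, the *ratio* H² is a nonlinear function
  and remains Jensen-biased at small panel sizes (≈ −0.07 at H² = 0.5 for
  10 × 3).  Recovery of the true value is therefore assessed on the
  component scale: unfloored component estimates are averaged across
  replicate panels and the means are plugged into the formula, which
  recovers truth to well under 0.05 across H² ∈ {0.2, 0.5, 0.8}.  Users
  comparing a REML fit should expect the same small-sample ratio bias.

The method-of-moments choice (rather than REML) keeps the module
deterministic and dependency-free; the estimators are simple closed forms
that a mixed-model fit can be checked against.

## Synthetic data: what it emulates, and what it does not

- **Wind** — clipped AR(1) at 1 s⁻¹ with Poisson-arriving exponential
  gusts feeding the innovation, base level offset so the stationary mean
  *including* gusts equals `mean_speed` (default 1.2 m s⁻¹, lag-1
  autocorrelation 0.7, one gust per 20 s of mean excess 0.8 m s⁻¹,
  innovation SD 0.25 m s⁻¹).  Speeds are clipped to [0, `max_speed`]
  (default 2.4 m s⁻¹): the generator emulates a gentle-condition session
  with coverage 0–2.4 m s⁻¹, and because the motion response is
  exponential in wind, an unbounded gust tail would let single excursions
  dominate every downstream correlation.  The AR(1)+gust form is the
  simplest process that clusters gusts the way wind eddies cluster
  windflecks; it is not an aerodynamic model.
- **Motion** — QOM(t) = a·exp(b·wind(t − lag))·m(t), with a = 0.002
  (still-air QOM), b = 1.2 (m s⁻¹)⁻¹, lag = 0.1 s, and m a unit-mean
  log-normal multiplier of CV 0.2, so the series is strictly positive.
  The exponential form mirrors the empirically observed motion–wind
  relation; there is no drag/stiffness physics and no resonance.
- **PPFD** — baseline (default 100 µmol m⁻² s⁻¹, mid-canopy shade) plus
  symmetric triangular pulses arriving with instantaneous rate
  `rate_gain`·QOM(t) (default 250 flecks s⁻¹ per QOM unit, giving a few
  flecks per second at typical motion).  Durations are log-normal with
  ~95 % of events between 0.05 and 0.44 s; amplitudes log-normal with
  median ≈ 40 µmol m⁻² s⁻¹; Gaussian sensor noise (SD 0.5) is added and
  the series clipped at 0.  Triangles make duration, intensity and
  integrated increase analytically checkable; real fleck shapes, penumbra
  and sun-angle effects are not modelled, and pulse peaks are snapped to
  the 0.01 s grid.  The ground-truth event list is returned with the
  series.
- **Frames** — three independent Gaussian-smoothed noise textures; the
  interior of each frame samples the texture shifted horizontally by the
  cumulative motion signal (sub-pixel shifts via linear interpolation)
  while a static border band serves as reference zones.  Pixel change is
  monotone in the per-frame displacement, which is what the closed-loop
  motion tests rely on; there is no 3-D canopy geometry, lighting change
  or camera noise unless added explicitly.
- **Traits** — value = grand mean + variety + block + residual effects,
  each Gaussian with the requested variance; one row per variety × block.
  The implied true H² is available in closed form for recovery studies.

Every generator takes an explicit integer seed and touches no global
random state: identical parameters give bit-identical outputs.

Because the generators share none of the analysis code, passing
closed-loop tests shows the chain is *internally consistent* (it recovers
what the generators injected) — it does not validate the biological
realism of any default, and field data with stabilization artifacts,
cloud passage or sensor drift will stress stages the synthetic streams do
not.

## Problem sizes and determinism

The verification suite uses sizes chosen to make the statistical checks
sharp while staying desk-scale: detector/oracle equivalence on 1000
random-walk series of length 500; clock-offset recovery on 240 s bundles
for 4 offsets × 20 seeds (tolerance ±0.05 s, i.e. ±5 samples at 100 s⁻¹);
heritability recovery on 2000 replicate 10 × 3 panels per true H²; motion
monotonicity across 12 displacement amplitudes at 64×64 px.  The pipeline
is deterministic for a fixed config and seed (per-stream seeds are derived
by hashing the master seed with stage indices), and the run-report records
the seed and a hash of the result-affecting configuration.

## Known limitations

- The detector's pruning rule ("remove smallest sub-threshold pair,
  merge, repeat") is one concrete reading of "sub-threshold oscillations
  were eliminated"; other readings (single-pass dropping) give slightly
  different event sets on pathological series.  The rule here is
  order-independent and validated against an independent oracle.
- The 16×9→zones cell map and the diffuser-proximity zone candidates are
  required user inputs; there is no image-based inference of either.
- A single constant shift per stream is assumed (no clock drift).
- Negative reference-corrected QOM is floored by default; whether the
  original field analysis floored is unknown, and the flag is exposed.
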