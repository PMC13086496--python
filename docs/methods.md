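# Methods

This note documents the statistical procedures, the generative model
behind the synthetic cohorts, the numerical conventions, and the design
choices made where more than one construction was defensible. Empirical
rates quoted here are the ones the test suite and `scripts/acceptance.py`
themselves compute.

## Data model

A heading track is one individual's azimuth time series in compass
degrees — clockwise from magnetic north, normalized to [0, 360) — with
strictly increasing timestamps. The acquisition hardware it models
samples at a nominal 5 Hz with a 0.9° encoder step, so valid recordings
sit on a 400-point angular grid; quantization checking is available but
optional, because derived tracks (e.g. rotated copies used in
equivariance checks) legitimately leave the grid. An experiment design
is an ordered, contiguous list of phases starting at t = 0, each with a
duration (default 300 s), a magnetic condition (NMF, the natural field,
or CMF, the field with its horizontal component reversed by 180°), a
visual-cue azimuth, and the expected seasonal direction. Under CMF the
direction a magnetic sense would report as the seasonal goal is the
expected direction rotated by 180°; a phase is in *cue conflict* when
that magnetic goal and the visual-cue azimuth disagree by more than 1°.

### Validation and preprocessing conventions

- CSV input is long-format (individual, time, azimuth, optional group),
  UTF-8, header required. Azimuths in [0, 360] are accepted (360 wraps
  to 0); anything else is rejected row-wise and reported rather than
  clamped, since out-of-range values indicate acquisition faults, not
  angles. Duplicate (individual, time) rows collapse to the first
  occurrence, counted in the validation report.
- All time windows are half-open, [start, end): a sample on a boundary
  belongs to the later phase or bin, so windows partition samples with
  no double counting.
- Flight cessations (stalls) are maximal runs of *unchanged* encoder
  readings lasting at least 10 s; equality is exact because the encoder
  quantizes. A run's end is the timestamp of the first differing sample
  (or one nominal sample period past the final sample at the end of a
  track), so a reading constant on [t, t+12) yields a 12-s interval.
  Individuals with more than 3 cessations are excluded (the
  fewer-than-four inclusion rule); cessation intervals are detected and
  counted but not masked from the analyzed samples by default, since
  masking is a separate, configurable decision.
- A time bin (and a trailing partial bin) is reported *undefined* when
  it holds fewer than 80% of its expected samples
  (duration × nominal rate). Undefined bins propagate as missing values
  rather than being silently computed from sparse data.
- The turn-rate stability metric samples the heading once per integer
  second — the first sample at or after each second mark, undefined if
  none arrives within 1 s — and averages the absolute minimal-angle
  difference between consecutive defined marks. It lies in [0, 180]
  deg/s and is invariant under global rotation. Which of the five
  per-second samples represents a second is not dictated by the data
  model; first-at-or-after is the documented choice.

## Per-individual statistics

The mean resultant vector of a sample of headings has north component
c = mean(cos θ) and east component s = mean(sin θ); the directedness is
r = √(c² + s²) and the mean direction atan2(s, c), reported as NaN
(never silently 0) when the resultant is numerically zero (< 1e-12).
Uniformity is tested with the Rayleigh statistic z = n r², with the
large-sample series approximation
p = exp(√(1 + 4n + 4(n² − R²)) − (1 + 2n)), R = n r, clamped to [0, 1].
With hundreds to thousands of encoder samples per phase this
approximation is accurate; the test suite checks it against a 10⁵-rep
Monte-Carlo null of r to within 0.02.

## Moore's modified Rayleigh test

Individuals are ranked by r ascending; ties receive average ranks (the
statistic was originally defined for continuous r, so some tie rule is
needed; average ranks keep the result deterministic and symmetric).
With ranks iⱼ and directions θⱼ, C = Σ iⱼ cos θⱼ, S = Σ iⱼ sin θⱼ,
R\* = √(C² + S²)/n^{3/2}, and the rank-weighted mean direction
MV = atan2(S, C). R\* is bounded by (n+1)/(2√n), attained exactly when
all directions coincide; a single-individual group is degenerate
(R\* ≡ 1) and triggers a warning rather than an error.

**Significance.** Rather than interpolating published critical-value
tables, p-values come from a seeded Monte-Carlo null: directions i.i.d.
uniform with ranks held fixed at 1..n (valid because under the null the
directions are independent of the r-ranking), with
p = (1 + #{R\*₀ ≥ R\*}) / (1 + n_mc) and empirical 95th/99th percentiles
as the significance radii. The null depends only on n, so one null
sample can be shared across phases, bins, and replicate cohorts of the
same size. Asymptotically R\*² → (1/6)χ²₂, i.e. P(R\* > x) → exp(−3x²),
putting the large-n 5% critical value just above 1.0 — the computed
value at n = 30 with 10⁵ draws is ≈ 1.02, which is why R\* > 1 works as
a visual significance threshold on time-series plots. The measured
type-I error at n = 20 over 10⁴ uniform cohorts is 0.048–0.050.

**Confidence arc.** The 95% CI for the MV direction is a percentile
bootstrap over individuals: resample the n (θ, r) pairs with
replacement (re-ranking each resample), reduce each bootstrap MV to its
signed deviation from the point estimate, and take the central 95% of
deviations, clamped so the point estimate always lies on the returned
clockwise arc. Degenerate resamples whose weighted resultant cancels
are redrawn and counted. The exact bootstrap construction used in prior
art is not standardized; this percentile-of-signed-deviation arc is one
defensible choice and is documented as such, not asserted as identical
to any particular script. Its measured coverage of the true goal
direction, for n = 25 cohorts of the control generator, is ≈ 93% —
the familiar mild under-coverage of percentile bootstraps at small n.

## Group comparisons

Benjamini–Hochberg adjustment uses the standard step-up with
monotonicity enforcement (delegated to statsmodels and verified against
a brute-force evaluation to 1e-12). Independent groups are compared
with the Wilcoxon rank-sum (Mann–Whitney) test, paired groups with the
Wilcoxon signed-rank test on individuals matched by id; exact p-values
are used for n ≤ 25 without ties, the normal approximation otherwise.
Identical paired samples (all differences zero) return p = 1 by
convention. The Friedman test covers repeated measures across phases;
for exactly two phases the same rank statistic with tie correction is
computed directly (the chi-square approximation with df = 1), since the
standard three-sample implementation does not apply. The compact letter
display assigns one letter per maximal clique of the non-significance
graph (pairs with adjusted p ≥ α, plus untested pairs, which are never
claimed different): any two groups that do not differ share a letter
and significantly different groups never do, which a greedy cover does
not guarantee. Clique enumeration is deterministic, ordered by group
name.

## Synthetic cohorts

The generator is a goal-biased wrapped random walk, Euler-integrated at
the encoder rate (Δt = 0.2 s):

    θ(t+Δt) = θ(t) + g_eff(t) · Δ(goal_i, θ(t)) · Δt + σ √Δt · ε,

where Δ(·,·) is the minimal signed angle difference, ε is standard
normal, and the result is quantized to the 0.9° grid for output (the
dynamics run unquantized; the encoder quantizes the measurement, not
the animal). Each individual's goal is the current phase's visual-cue
azimuth plus a personal offset drawn von Mises(0, κ). During a
contiguous run of conflict phases the gain decays as
g · exp(−(t − t_onset)/τ) — modelling a recognition time for the cue
conflict — and is restored immediately when the cues re-align.
Alternatives (hard switching, thresholds) are deliberately out of
scope: the model is the simplest mechanism that produces gradual,
delayed disorientation.

Reproducibility: one master seed; each individual draws its offset,
initial heading, and noise stream from its own spawned substream, so
cohorts are bit-reproducible and order-independent (simulating
individual i alone equals column i of the cohort).

| parameter | units | default | rationale |
|---|---|---|---|
| gain g | 1/s | 0.5 | heading relaxation time 1/g = 2 s: brisk but not instantaneous corrective steering |
| noise σ | deg/√s | 10 (45 without cues) | stationary angular sd σ/√(2g) ≈ 10° for oriented flight; 45 gives free diffusion that wraps the circle within a phase |
| goal scatter κ | – | 8 | per-individual goal offsets with sd ≈ 21°, a clearly oriented but not lockstep cohort |
| decay τ | s | 45 | calibrated (see below) |
| cohort size | – | 25 | typical for this assay family |
| phases | s | 5 × 300 (4 × 300 without cues) | the standard trial layout |

**Calibration of τ.** τ is the one parameter tuned to a qualitative
target: orientation significant throughout phase II's first bins,
lost during phase III, regained by phase V. In this model group
orientation collapses only once the decayed gain falls below the
diffusion scale (g_eff ≲ σ²/2·(120°)⁻², after ≈ 5τ) *and* free
diffusion has had ≈ σ⁻²·(120°)² s to disperse headings; a coarse sweep
over τ ∈ {30, 45, 60, 90} s showed τ ≥ 60 s leaves phase III partially
oriented while 30–45 s reproduce the signature in ≈ 90% of cohorts.
τ = 45 s is the preset. This is calibration to a phenomenon, not an
inference about any animal.

**The control preset** keeps cue and magnetic goal congruent in all
five phases by holding the natural field; a congruent design that
alternates the field while moving the cue is generatively equivalent,
because only the conflict flag and the cue azimuth enter the dynamics.
**The no-visual-cue preset** sets g = 0 with σ = 45 over four 300-s
phases: headings diffuse freely, yielding low directedness and a
many-fold higher turn rate.

**What the generator does and does not emulate.** It reproduces the
sampling rate, quantization, phase structure, goal-concentrated
individual vectors, delayed group-level disorientation, and the
stability contrast. It does not model biomechanics, wind, closed-loop
torque, stalls/cessations (synthetic tracks never stall), motivation
drift, or any magnetoreception mechanism; its individual directedness
under the oriented presets (r ≈ 0.98) is higher than typically observed
in real animals (r ≈ 0.5–0.95), because a single diffusion term cannot
produce both tight within-phase headings and occasional excursions.
Passing recovery tests on these cohorts therefore demonstrates
correctness of the statistical chain under a favorable, known-truth
data-generating process — not performance on noisier field data.

## Problem sizes used by the checks

The test suite and acceptance script use: 10⁵-draw Monte-Carlo nulls
for critical values; 10⁴ uniform cohorts (n = 20) for type-I error;
1000 replicate control cohorts (tests; 400 in the acceptance script)
for goal recovery and bootstrap coverage at n = 25; 100 replicate
conflict cohorts for the delayed-disorientation rate; 20 individuals
per group for the stability contrast; and 100 random instances for the
brute-force oracle comparisons at 1e-12. Replicate counts were chosen
to keep the binomial standard error of each estimated rate well below
its margin to the asserted threshold.

## Known limitations

- The Rayleigh p approximation degrades below n ≈ 10 samples; encoder
  data is far above this, but hand-built toy slices may not be.
- The bootstrap arc under-covers by ≈ 2 points at n = 25; bias-corrected
  variants were not implemented.
- R\* values are comparable only at equal cohort size; the time-binned
  series drops individuals with undefined bins, so n can vary by bin
  and is reported alongside each value.
- The letter display can assign multiple letters per group when the
  non-significance graph is not transitively closed; that is a property
  of the data, not an error.
- Cessation handling counts stalls for inclusion but does not model the
  experimenter intervention that ends them, and analyzed phase vectors
  include stall samples unless explicitly masked upstream.
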