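# Methods

This note documents the models implemented in `dvmotifs`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real recordings.

## Coordinates and containers

All times are milliseconds relative to saccade initiation at t = 0.  The
analysis epoch is [−750, 0) ms in 15 nonoverlapping 50-ms bins labeled by
their left edge.  A session is a trial table (orientation, contrast, prior
context, mapping rule, choice category, saccade direction, accuracy, event
times) plus a unit × bin × trial array of spike counts.  Units whose
task-wide mean rate falls below 3 ips are excluded before decoding.

## Decision-variable decoding

Within every bin, each unit's counts are z-scored across trials.  For a
binary labeling (categorical: CW vs CCW choice; motor: right vs left
saccade) the decoder weights solve `Σ w = s`, with `s` the difference of
the two choice-conditioned mean z-scored patterns and `Σ` the covariance
matrix of the z-scored responses — the discriminant direction of a
multivariate-Gaussian read-out.  Notes:

- `Σ` is the **total** covariance (all trials), not the pooled
  within-class covariance.  For two classes the two matrices give exactly
  proportional solutions (a rank-one update of the within-class matrix by
  the outer product of `s`), so the decoded direction is identical; the
  test suite exploits this by checking unit-normalized weights against an
  independent LDA solve.
- `Σ` is shrunk toward its diagonal, `(1−λ)Σ + λ diag Σ` with λ = 0.1 by
  default.  Real ensembles (tens of units, thousands of trials) rarely
  need it; small synthetic instances do.  λ = 0 recovers the plain solve.
- Zero-variance unit/bins get z-score 0 and weight 0 by convention.

Per-trial DVs are strictly cross-validated: trial j is projected on
weights — and, by default, z-scoring statistics — estimated from all
trials except j.  (A permissive variant z-scores once on all trials;
strict is the default because the z-scoring statistics are part of the
fitted decoder.)  The leave-one-out sweep uses rank-one downdates of the
count sums and one batched linear solve per bin, so the exact computation
costs about the same as a single fit.  Overall decoder performance is
additionally summarized on a single 750-ms counting window.

Condition-averaged trajectories are formed per behavioral outcome
(2 categories × 2 directions), or by stimulus strength × accuracy, by
congruency with the prior, or on zero-signal trials only.  "Unsigned"
trajectories invert the CCW (categorical) and left (motor) trajectories so
everything rises positively.  DVs stay in decoder (z-based) units; shapes,
not absolute scales, carry the scientific content.

## Motif models

A motif is the joint temporal pattern of the categorical and motor DV for
one choice-conditioned trajectory pair.  Rises are cumulative Gaussians
`v(t) = offset + range·Φ((t−t50)/τ)` with `range` sign-free:

| model         | k | structure |
|---------------|---|-----------|
| intentional   | 4 | categorical ≡ 0; motor rises (offset, range, τ, t50) |
| abstract      | 9 | categorical rises (5 params incl. decay) then motor (4); `t50_m ≥ t50_c + 250 ms` |
| mixture       | 7 | shared τ and t50; per-dimension offset and range; categorical decay |
| unconstrained | 9 | abstract equations without the ordering bound |

After the categorical rise reaches its 99.38th percentile
(`t_peak = t50 + 2.5006 τ`) the categorical value is multiplied by
`exp(−(t−t_peak)/τ_decay)` — a single time constant decaying toward zero.
The intentional model is read literally: all four parameters belong to the
motor dimension.  The mixture model's seven parameters are the unique
allocation consistent with a shared rise: 2 shared + 4 offsets/ranges + 1
decay.

Fits minimize the summed squared error of the trajectory pair (n = 30
points) by bounded least squares (`t50 ∈ [−750, 0]` ms, τ ∈ [5, 500] ms,
decay ∈ [10, 2000] ms; the abstract ordering constraint is a box bound via
`t50_m = t50_c + 250 + sep`, `sep ≥ 0`).  Multi-start: one data-driven
initialization (half-rise crossing heuristic) plus Latin-hypercube draws
within the bounds; random escape starts run under a capped iteration
budget and the best is polished to tolerance 1e−10.  Model comparison uses
`AIC = 2k + n ln σ̂²` with `σ̂² = SSE/(n−k)`; only ΔAIC is meaningful (the
data constant cancels).  Onset = `t50 − 1.6449 τ` (5th percentile), with an
absolute-threshold variant (first crossing of a fixed DV level) as a
range-independent complement.  Peak-time uncertainty comes from refitting
bootstrap resamples of the trials (library default 1,000 resamples;
bootstrap refits warm-start at the point estimate).

## Deliberation signatures

**Variance partition.**  Per bin and DV dimension, with the dimension's
own choice labeling and the stimulus orientation as factors,
`Σ_k (DV_k−m)² = Σ_k (m_choice(k)−m)² + Σ_k (m_cell(k)−m_choice(k))² +
Σ_k (DV_k−m_cell(k))²` — an exact identity for nested means, checked to
1e−10 on random instances.  The residual fraction's timecourse carries the
diffusion signature: under temporal integration of noisy evidence it rises
during accumulation in the categorical DV only.

**DV bias.**  Congruent trials are those whose *chosen category* matches
the block's over-represented category.  Per stimulus-strength level
(|orientation|), the unsigned congruent and incongruent trajectories are
averaged and differenced; level differences are averaged with equal
weights so strength composition cannot masquerade as bias.  "Neural
expectation" is the bias read out 500 ms before the saccade (a grid bin;
±2-bin sensitivity analysis included), computed per contrast and
dimension.  Across sessions it is rank-correlated with the behavioral
decision bias, with permutation p-values.

## Geometry

The angle between the categorical and motor weight vectors per bin is the
arc-cosine of their normalized inner product (degrees, 0–180; zero-norm
vectors flagged NaN); sessions are aggregated by circular mean.  The same
measure against a reference bin (default: last pre-saccadic) quantifies
plane stability.  Trial-wise cross-correlation: both DV series are
mean-subtracted per trial, correlated at lags up to ±500 ms (biased
normalization by the full-series norms; ≥5 overlapping bins), averaged by
mapping rule, and corrected by subtracting the session's global average
curve.  The sign convention pairs the categorical DV at t+lag with the
motor DV at t, so a leading categorical signal peaks at negative lag.  The
null band re-pairs each trial's categorical series with the motor series
of the next trial within rule (circular, extended to further shifts for a
percentile band) — autocorrelation is preserved, trial identity severed.

## Behavior

`p(CW|θ) = λ/2 + (1−λ)Φ((θ−μ)/σ)` fit by maximum likelihood (Bernoulli),
lapse applied symmetrically and fit freely within [0, 0.5]; orientation
sensitivity is 1/σ.  The prior-bias variant shares σ and λ across the two
prior contexts with prior-specific means; decision bias is |μ₁−μ₂|
(signed internally).  Optimization is bounded L-BFGS-B with 5 random
restarts — the lapse/slope trade-off creates local minima, and at the
task's narrow stimulus range (±3.3°) λ and σ are weakly identified, which
is why recovery guarantees are stated as medians over sessions.
Uncertainty: 100-fold nonparametric bootstrap, summarized by IQRs;
degenerate resamples are rejected and counted.

## Synthetic sessions

The generator emulates the task: seven orientations (−3.3…+3.3°), two
mapping rules drawn per trial, 80-trial prior blocks and 100-trial
contrast blocks alternating with random phase (distinct lengths keep the
two factors unconfounded), skewed priors defaulting to 75/25 side mass
with 1/7 on vertical, event times with 0–65 ms uniform jitter, random
feedback on vertical stimuli.

The latent process is Euler-discretized (5-ms steps, ≥10 per analysis bin)
bounded accumulation on the categorical axis: start at the prior- and
contrast-specific offset (expectation as a starting point, not a drift
bias — the DV bias is present before stimulus onset), drift =
drift_gain × orientation, diffusion noise, absorption at ±bound.
Commitment occurs at the bound hit, or at a deliberation deadline
(`rotation_delay_ms` after accumulation onset) when the bound is not
reached; the categorical latent then decays exponentially.  The transfer
onto the motor axis is gated at the fixed deadline — the response can only
be released at the go cue — so the motor latent ramps (90° at constant
angular speed, default 600°/s → 150 ms) to a stereotyped amplitude with a
weak echo (`motor_gain`) of the committed categorical state.  This
separation is deliberate: per-trial commitment times make the categorical
peak accuracy- and strength-dependent (the bound signature) while the
motor trajectory stays stereotyped, which is exactly the asymmetry the
analyses must detect.  A `motor_lag_ms` option replaces the ramp by a
rule-signed delayed copy of the categorical latent, used to calibrate
lag-recovery analyses with an exactly known lag.

Emissions are Poisson per 50-ms bin with rectified-linear rates
`max(0, baseline + a·x_c + m·x_m)`; baselines are gamma-distributed
(mean 10 ips, floor 3 ips) and the categorical/motor loadings are
independent normals — mixed selectivity with no relation between preferred
category and preferred direction, making the two decoded dimensions
orthogonal in expectation.

Default scales: bound 0.5, noise 1.0 √s⁻¹, drift gain 1.0 (high contrast)
and 0.45 (low) evidence·s⁻¹·deg⁻¹, starting offsets 0.08/0.16
(high/low contrast), accumulation onset −600 ms (jitter 0–30 ms),
deadline/rotation delay 300 ms, categorical decay 300 ms, 30 units,
loading sd 6 ips per evidence unit.  These were chosen so the generator
reproduces the task's phenomenology rather than any particular number:
most trials commit at the bound before the deadline; easiest-stimulus
accuracy ≈ 95–98%; orientation sensitivity roughly halves at low contrast
and the decision bias grows; and the 750-ms decoder reaches ≈ 0.85–0.9
(categorical) and ≈ 0.99 (motor) held-out accuracy, i.e. clearly decodable
choices with the motor dimension near ceiling shortly before the saccade.
A single seed expands into per-stage child seeds (trials, latents,
emissions), so identical configurations reproduce bitwise.

What the generator does **not** emulate: spike-train autocorrelation
beyond the latent process (counts are conditionally independent across
bins), firing-rate adaptation, recording instabilities, cross-unit noise
correlations beyond the shared latent, saccade-latency variability tied to
commitment time, and any nonlinearity in the population read-out.  Passing
the suite therefore shows the *analyses* are correct and well calibrated
on a process with the hypothesized structure — not that real cortex obeys
that structure.

## Validation experiments and problem sizes

`dvmotifs.experiments` (run by `scripts/acceptance.py` and the test suite)
regenerates everything from scratch: decoder weights vs an independent LDA
oracle (100 random instances, agreement to 1e−8 after unit-norming);
partition conservation (1,000 instances plus a 4-trial hand-worked case);
motif t50 recovery (100 noisy repetitions, noise sd = 0.1 × range, median
error ≤ 25 ms); model-selection calibration (100 sessions per generating
motif); onset-order recovery (50 decoded sessions, 200-ms rotation delay);
deliberation signatures (20 sessions × 1,600 trials — the accuracy-split
peak analysis needs the task's real session scale — with a 60-resample
peak-time bootstrap per session); geometry (20 + 20 sessions, embedded
100-ms lag); expectation linkage (30 sessions × 640 trials, offsets drawn
uniformly, 2,000 permutations); psychometric recovery (100 sessions ×
2,000 Bernoulli trials); and a bitwise determinism check of the pipeline.
Other experiments use 320–640-trial sessions with 30 units; directional
claims use one-sided sign tests at the 15/20 binomial criterion.

## Known limitations

- The decay multiplies the full categorical value (offset included), so
  motif optima are only approximately covariant under additive shifts of
  the data; ΔAIC orderings are unaffected in practice.
- With few trials, a contrast block can miss one prior context; the
  prior-bias fit then raises a documented degenerate-fit error (the
  pipeline records it and continues).
- The response-field null interval is a Poisson parametric bootstrap on
  the pooled mean; overdispersed real units would need a renewal or
  negative-binomial null.
- The cross-correlation normalization is the biased estimator; lags are
  restricted to |lag| ≤ 500 ms with ≥ 5 overlapping bins.
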