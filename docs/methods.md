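# Methods notes

This note documents the models, defaults and numerical choices behind
`gaitprint`, and what the synthetic cohort does and does not emulate.

## Synthetic GRF cohort

The generator emulates a level-running study: a cohort of subjects, each
recorded in four footwear conditions (barefoot and three standardised
shoes), ten trials per condition, one right-foot stance per trial on a
1 kHz force plate. The default design is 30 x 4 x 10 = 1,200 recordings.

**Signature model.** Every subject carries nine shape parameters (the
"movement signature"): vertical impact-peak magnitude (%BW) and timing
(%stance), active-peak magnitude and timing, AP braking- and
propulsion-peak magnitudes, ML oscillation amplitude and phase, and stance
duration (ms). Population means/SDs are typical rearfoot-running values —
impact peak 160 ± 20 %BW at 15 ± 2.5 %stance, active peak 250 ± 20 %BW at
45 ± 3 %stance, AP peaks 25 ± 5 %BW, ML amplitude 8 ± 3 %BW, stance
250 ± 25 ms — and body mass is uniform on 71.4–100.0 kg. Three scales
govern the data-generating process and default to 1:

* `between_subject_scale` multiplies the between-subject SDs *and* the
  body-mass spread (mass is a subject property; at scale 0 every subject
  is statistically identical);
* `between_footwear_scale` multiplies the per-condition signature offsets
  and the shoe-mass weight delta;
* `trial_noise_scale` multiplies parameter jitter per trial, a smooth
  low-frequency shape residual, and white sensor noise.

Sensor noise is specified in %BW (about 0.4–0.5 N here) rather than
newtons. This is deliberate: body-weight normalisation then cancels it
identically across subjects, so switching an effect scale to zero really
removes all information about that factor. The one remaining absolute
quantity — the 10 N stance threshold — is itself a genuine, tiny subject
cue at nonzero mass spread (heavier runners cross it earlier in %stance),
which is faithful to real force-plate processing.

**Curve templates.** Channels are sums of smooth lobes on the stance
fraction t ∈ [0, 1], edge-tapered to zero over the first/last 3%:

* V: impact Gaussian (σ = 4.5 %stance) + active Gaussian (σ = 13 %stance)
  over a broad flat-top plateau (9% of the active peak). The plateau keeps
  the vertical force above the 10 N threshold until ≈99% of the configured
  stance — a pure two-Gaussian shape decays too early and would make
  threshold-detected stance ~12% shorter than configured. Lobe amplitudes
  are overlap-corrected so the curve attains the configured peak values at
  the configured times exactly; the stance-mean vertical force lands near
  one body weight.
* AP: negative braking and positive propulsion Gaussians of equal width at
  25% and 75% of stance; equal magnitudes give a (numerically) zero net
  AP impulse by symmetry.
* ML: a 1.5-cycle sinusoid with subject-specific phase and a positive
  (lateral) mean offset of 0.3 x amplitude.

Sign conventions (the raw data carry none): V ≥ 0, AP braking negative /
propulsion positive, ML mean-positive lateral. Channel order is (ML, AP, V)
everywhere.

**Footwear profiles.** `"default"` spreads condition offsets over impact
magnitude/timing, active peak, AP peaks, ML amplitude and stance duration
(barefoot: harder/earlier impact, shorter stance; the cushioned shoe the
reverse); `"ap_only"` puts condition information exclusively into the AP
peak magnitudes, which is the designed ground truth for relevance
localisation experiments.

**Randomness.** Cohort parameters derive from `rng_seed`; each trial uses
a stream seeded by (seed, subject, condition, trial), so single trials are
reproducible without replaying the cohort. Identical configs give
bit-identical datasets.

**What the generator does not emulate:** running speed and its
within-session drift, bilateral asymmetry, fatigue, kinematic coupling,
non-stationary sensor drift, multi-plate targeting artefacts, or
subject-by-footwear interactions (condition offsets are additive and
identical for everyone). Passing tests therefore demonstrate that the
pipeline recovers the effects the generator encodes, not that real cohorts
behave this way — in particular, real subject recognition across footwear
is harder than the additive model suggests.

## Preprocessing

Butterworth design at order 2, cut-off 50 Hz, run forward and backward
(`filtfilt`), which squares the magnitude response and cancels phase; no
cut-off correction is applied for the double pass, matching the
conventional reading of "2nd-order bidirectional at 50 Hz". Edge handling
is reflective padding of length 3 x order — fixed so results are exactly
reproducible. Stance is the longest contiguous run of filtered V strictly
above 10 N (earliest run on ties). Time normalisation is piecewise-linear
interpolation onto 101 evenly spaced points spanning the detected stance —
the least-assumption interpolant, validated against an analytic sinusoid
oracle. Min–max scaling is per input (303 independent scalers), fitted on
training data only; constant training inputs map to 0, test values are not
clipped. Per-channel or global scaling variants were considered and
rejected: per-input is the standard ML reading and keeps every input
comparable inside the SVM margin.

## Classification

`LinearStanceSVM` couples the scaler and a liblinear L2-regularised,
squared-hinge, one-vs-rest linear SVM (primal formulation; deterministic
given data). Defaults: tol 1e-4, max_iter 5000, solver seed recorded.
One-vs-rest is required downstream: relevance propagation needs one weight
vector per class.

Outer folds are task-aware (see README). Inner model selection uses a
two-fold split obeying the same disjointness rule; for the subject task an
even footwear-disjoint 2-fold split of three training conditions is
impossible, so one inner fold holds one condition and the other two, and
both directions are averaged — the closest realisable analogue. Grid-search
ties resolve to the smallest C (strongest regularisation); zero-rule ties
to the first-encountered label. The headline statistic is the median over
the four outer folds. `CVReport` carries both the per-fold training-set
zero-rule baseline and the whole-design class-structure baseline; with 10
trials per cell split 3/3/2/2 the former is 8/900 ≈ 0.9% for the pair task
while the class-structure value is 1/120 ≈ 0.8%.

The full 81-value grid C = 2⁻⁵ … 2¹⁵ (step 0.25 in the exponent) is the
library default. Repeated-simulation studies in the test suite and the
acceptance script use coarser sub-grids of the same range (exponent steps
2.5–5): the chance-level and effect-recovery conclusions are insensitive to
grid resolution, and this keeps multi-seed runs at the full 1,200-recording
design to a few minutes each.

## Relevance propagation

For linear models the relevance of input i to class k is R_i = x_i w_{k,i}
(no bias distribution; the identity Σ R_i = score − b holds exactly and is
asserted at 1e-9 relative tolerance). The decomposed class is always the
ground-truth class, and each recording is decomposed with the model of the
outer fold in which it was test data. Negative scores are discarded and
each trial's map is normalised to its own maximum before aggregation; raw
positive aggregation is available as a toggle. The normalisation scope is
per trial (the most local reading of "respective maximum"); per-trial
normalisation flattens the relevance landscape somewhat — in localisation
experiments the raw positive aggregate concentrates ≥50% of its mass in
the designed discriminative window, the normalised one roughly twice the
window's uniform share — which is the price of comparability across trials.

## Statistical evaluation

The time-continuous comparison is a pointwise one-way ANOVA (trials pooled
within condition, every curve treated as independent; the repeated-measures
structure is not modelled) with family-wise error control by permutation:
condition labels are permuted whole-curve-wise, the maximum F over the 101
points is collected (observed labelling included as one permutation), and
F* is the (1 − α) upper order statistic. This permutation scheme replaces
random-field-theory thresholds on purpose: it is assumption-light, exact up
to Monte-Carlo error, and validated here by a type-I-error study (fraction
of null datasets with any cluster ≤ α + 2 SE at 200 replicates). Defaults
α = 0.05, n_perm = 1000 (threshold resolution 0.001; runtime well under a
second per channel).

Discrete peak variables use fixed search windows, since published curve
figures mark peaks without defining them: V impact peak = first local
maximum in (0, 33] %stance (may be absent — reported as missing, not an
error), V active peak = global maximum after the impact peak, AP braking =
global minimum in (0, 50], AP propulsion = global maximum in (50, 100), ML
extrema over full stance, ties to the earliest index. Kruskal–Wallis is
tie-corrected with chi-squared p-values (all-identical data returns H = 0,
p = 1 rather than an error). The DSCF post-hoc computes pairwise Wilcoxon
rank sums on each pair alone, with tie-corrected variance, and refers
√2 |z| to the studentized-range distribution with k groups (infinite df);
pairs with fewer than two values per group are marked untestable.

## Problem sizes used in the automated checks

Unit tests run on a 4 x 4 x 3 cohort; parameter-recovery and
chance-level studies use the full default 30 x 4 x 10 design over five
cohort seeds with sub-grid model selection; the SPM type-I study uses 200
replicates of 4 groups x 8 curves with 200 permutations each. The
acceptance script runs the default design once per task with an
exponent-step-2.5 grid.

## Known limitations

* Additive, interaction-free effect model in the generator (see above).
* The SPM ANOVA ignores the within-subject pairing of conditions.
* The inner split for the subject task is structurally uneven (1 vs 2
  conditions), which biases inner accuracy estimates slightly low; it is
  used only to rank C values.
* Liblinear at very large C on near-separable data can stop at max_iter;
  the tolerance/iteration caps are recorded in the model parameters.
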