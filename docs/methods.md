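# Methods

This note documents the generative model behind the synthetic sessions,
the estimators, the numerical conventions, and the design decisions that
were genuinely open — the information a maintainer needs to interpret what
a passing test suite does and does not establish.

## Generative model

A session is a trials × time-bins × features tensor of 20 ms-binned
activity.  Features come in two streams per electrode (threshold-crossing
counts and spike-band power), generated as two noisy readouts of a single
latent per-electrode signal; the default 128 features correspond to a
64-electrode array.  Each trial has four epochs — pre-cue, cue listening,
preparatory delay, speech (from the go cue) — with uniformly jittered
delay and reaction times.

The latent mean for a condition with consonants (c₁..c_S) in epoch *e* is

```
μ = baseline
  + e_gain[e] · Σ_s g_s · t_s · b_s[c_s]      (phoneme code)
  + L · length_axis + 𝟙[two words] · boundary_axis
  + private_e(c₁..c_S) + block drift
```

where `g_s` is a position gain, and `t_s` is the word-boundary truncation
factor: during the preparatory epoch only, slots after the first word
boundary are scaled by `boundary_gain ∈ [0,1]` (0 = the second word is not
prepared at all).  The length and boundary axes switch on at cue onset —
before the cue plays the condition cannot be reflected in the activity —
but are not scaled by the epoch gains.

**Phoneme-vector geometry.**  Within a position the *m* phoneme vectors
sit at the vertices of a regular simplex: unit norm, zero-sum (the
identifiability gauge of a one-hot + intercept model), mutually
equidistant.  Each position maps the simplex into feature space through a
frame `A_p` built from disjoint orthonormal blocks combined by a factor of
the target cosine matrix `C`, so that `A_pᵀA_q = C[p,q]·I`.  Like-phoneme
vectors at positions *p,q* then have cosine exactly `C[p,q]`; the matrix
must be a valid Gram target (unit diagonal, positive semidefinite), which
is validated at construction.  The length axis, boundary axis, and any
epoch-private code occupy further orthogonal directions; construction
fails with a clear error if the electrode count cannot host them all.

**Epoch structure.**  By default the phoneme code is shared across epochs
(epoch gains 1, no private code), so decoders transfer perfectly across
cue/preparation/speech up to noise.  Setting the shared epoch gains to 0
and `epoch_private_scale > 0` replaces it with *per-epoch* phoneme codes
in mutually orthogonal subspaces — full condition-tuned codes, not
unstructured nuisance — which makes within-epoch decoding strong while
cross-epoch transfer drops to chance.  This is the knob that makes both
outcomes of the epoch-generalization analysis testable.

**Conjunctive (per-sequence-random) null.**  `style="conjunctive"` draws
an iid random mean per condition and projects out the positional-additive
component (intercept + slot-phoneme one-hots + two-word flag) within each
length family, then rescales all residuals by one common factor to match
the compositional code's signal power.  The surviving code is purely
conjunctive: no additive model can explain its condition means, by
construction.  Its length and boundary axes are zeroed for the same reason
— a systematic length offset is itself compositional structure and would
hand the compositional predictor unearned variance.

**Noise and SNR.**  Noise has a trial-level component (sd 1, shared by all
bins of a trial — slow population variability) plus independent per-bin
noise in each stream (sd 1) and a per-block drift offset (sd 0.2,
mirroring the block-mean subtraction in preprocessing).  `snr` is defined
as the norm of a unit-gain per-position phoneme pattern divided by the
trial-level noise sd: the trial-level term is the noise floor that
survives window averaging, so this is the SNR that actually governs
decoding of window-averaged features.  A generator with purely per-bin
noise would let every analysis hit ceiling once windows average a couple
dozen bins, and graded phenomena (partial cross-position transfer, AUC in
the 0.7–0.95 range) would be untestable.  An optional Poisson-count mode
clips latent rates at zero and draws integer counts (variance ≈ mean,
property-tested); every shipped analysis operates on z-scored features, so
Gaussian mode is the default.

**Default condition values** (chosen once, on field-typical grounds):
cross-position alignment 0.6 off-diagonal (adjacent-position coefficient
cosines near 0.6 are the empirically reported regime); position gains
`1 − 0.1(s−1)` floored at 0.5 (tuning weakens for deeper slots); length
axis norm equal to `snr` (yields multi-class normalized balanced accuracy
near 0.6–0.7); boundary axis norm 1.5×`snr` (the one- vs two-word contrast
is a large effect at the single-electrode level); 15 repeats per condition
(a few hundred to ~1000 trials per session, the scale of real sessions).
Heavier analyses use more repeats purely for estimator precision: 20 for
epoch generalization, 12 × 162 conditions for the word-boundary set, 30–60
where condition-averaged R² or coefficient cosines are the endpoint; these
sizes were fixed by a power analysis of condition-mean standard errors,
not tuned per run.

## Estimators and conventions

**Diagonal LDA.**  Between-class scatter `B = Σ n_k(μ_k−μ)ᵀ(μ_k−μ)`;
within-class scatter is reduced to its diagonal `d`, floored at
`1e−8 + 1e−6·mean(d)` to guard zero-variance features.  The eigenproblem
`D⁻¹B` is solved exactly via SVD of the whitened class-mean matrix
(O(F·K²)); exactly K−1 components are kept, ordered by descending
eigenvalue, each column's largest-magnitude entry made positive.  Binary
discriminant scores are the inner product with the projected class-mean
difference relative to the midpoint; the logistic map to probabilities is
untempered (AUC is invariant to any monotone rescaling — tested).

**Leave-one-out recentering.**  In LOO, removing the test trial makes the
two class means unequally noisy; the midpoint term
`½(‖m̂₁‖² − ‖m̂₀‖²)/d` then carries an estimation bias that pushes
chance-level AUC far below 0.5 in high dimensions (≈0.41 at 8 trials/class
× 128 features).  The LOO scorer subtracts the exact expectation of that
bias, `½Σ_f (v̂₁_f/n₁ − v̂₀_f/n₀)/d_f`, computed from training-fold
statistics only.  A property test confirms chance AUC ≈ 0.5 on label-free
data; a small negative skew bias (~0.01–0.03) remains below ~12
trials/class, which is why chance-level assertions use sessions of
scenario size.

**Cross-validation.**  Stratified folds are seeded and deterministic, with
an optional separate stratification variable (e.g. folds balanced over
full sequences while decoding a coarser label).  Held-out scores are
pooled across folds before computing AUC, except the word-boundary
classifier, where AUC is averaged across folds with a normal-approximation
CI (±1.96 × sd over folds) — both conventions exist in the source
procedures and both are exposed.

**R² metrics.**  Encoding-model R² is computed on pooled held-out
predictions: single-trial R² as the uniform average of per-feature R²
(each electrode weighted equally), condition-averaged R² on group means
after marginalizing the 1st slot.  In discriminant-component space
(compositional predictor) R² is a single multivariate statistic, which
weights each component by its variance.  Caveat: *pooled*
condition-averaged R² is positively biased under label shuffles, because
predictions are trained on trials that also enter the observed group
means; it is therefore always reported with its permutation p-value, and
chance-level (sentinel) assertions use the single-trial metric, which is
unbiased at chance.

**Compositional predictor.**  For each held-out (length, 1st-consonant)
class: prediction = length mean + like-consonant displacement from donor
lengths, rescaled by the ratio of mean displacement norms estimated
without the held-out class (the simplest rule consistent with "scaled for
magnitude differences"; it is a pluggable choice).  The length mean uses
all conditions of that length — excluding the held-out class would bias it
by −d/(m−1) and a noiseless compositional code would no longer be
predicted exactly.  Donor predictions are averaged when several lengths
exist.

**Windows and timing.**  All times are seconds relative to an alignment
event; windows are half-open `[start, end)`; bin 0 starts at the event.
Preparatory window lengths differ by analysis (0.5–0.8 s before the go
cue) and are explicit arguments with those defaults.  PSTH smoothing uses
a Gaussian kernel (σ = 60 ms = 3 bins) truncated at ±4σ with renormalized
partial kernels at the edges, so constants are exactly preserved.
Peak-time anchoring for cross-epoch analysis takes the first maximum on
ties and clips the 0.5 s peak-centered window inside the swept epoch
range.  The cross-time matrix reports (never silently applies) a
minimum-trials mask, defaulting to the 900-trial rule with the threshold
configurable because synthetic sessions are smaller.

**Statistics.**  Welch tests report Δ ± SE_Δ with
`SE_Δ = sqrt(s₁²/n₁ + s₂²/n₂)` and Welch–Satterthwaite degrees of freedom.
BH-FDR is applied over explicitly named families (positions × arrays,
channels × cues, ...), never implicitly.  Permutation p-values use the raw
fraction of null draws ≥ observed, with the resolution floor `1/n_perm`
reported so "p < 1e−4" statements are reproducible; bootstrap CIs are
percentile intervals with seeds, and undefined resamples are dropped and
counted.

## What the synthetic sessions do and do not establish

The generator realizes the analyses' own modeling assumptions: linear
compositional (or conjunctive) codes, Gaussian trial noise, stationary
epochs, balanced designs.  Passing tests therefore establish that the
estimators recover the truth *when the model holds* — parameter recovery,
correct chance levels, correct error control — and that the pipeline
distinguishes compositional from conjunctive codes.  They do not establish
anything about real tissue: real recordings have non-stationary tuning,
correlated noise with structure beyond a trial-level offset, unbalanced
trial counts, annotation errors in speech onsets, and no guarantee of
linearity.  Quantities like "95% condition-averaged R²" are properties of
the simulated regime, not predictions for new neural data.

## Known limitations

- The LOO chance-level recentering is exact in expectation but leaves a
  small rank-skew bias below ~12 trials per class; very small pair
  analyses should prefer stratified k-fold.
- The conjunctive null zeroes single-slot (length-1) condition structure
  entirely, since one-slot sequences are trivially additive.
- `marginal_correlation_matrix` returns NaN rows for zero-variance group
  vectors rather than imputing.
- The CLI report is text-only; plotting is left to the caller.
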