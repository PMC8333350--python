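# Methods

This note documents the modelling and numerical choices behind `neuronorm`:
what the normative model assumes, what the synthetic-data generator does and
does not emulate, and where the design was genuinely open.

## Normative model

The healthy-population model is a conditioned adversarial autoencoder over
101 regional brain volumes.  Its premise: a network trained to reconstruct
only healthy controls will reconstruct new controls well and reconstruct
pathological morphometry poorly, so the mean squared reconstruction error
over the 101 normalised regions acts as a per-subject anomaly ("deviation")
score.  Conditioning the decoder on one-hot age and sex removes those
demographics from what the latent code must carry, so deviation reflects
departure from the *age- and sex-appropriate* norm.

Architecture: encoder 101 → 100 → 100 → 20 (linear latent), decoder
(20 + 27 + 2) → 100 → 100 → 101 (linear output), discriminator
20 → 100 → 100 → 1 (sigmoid).  Hidden activations are leaky ReLU
(negative slope 0.01, configurable).  The latent prior is a standard normal
on the 20-dimensional code; the discriminator receives only latent/prior
samples, not the condition vector.

### Training

Features: volumes are divided by total intracranial volume, then each
region is centred on the training-set median and scaled by its training-set
interquartile range (quantiles by linear interpolation between order
statistics).  The scaler is part of the trained model: the same statistics
normalise clinical data, and each bootstrap iteration refits them on its
own resampled training set.  Age is integer years in 47–73 (fractional
ages are rejected rather than rounded, since the one-hot encoding is
defined on integer years); position `age − 47` of the 27-vector is set.
Sex is encoded (male, female).

Each minibatch (size 256, 200 epochs, Adam with standard moments
0.9/0.999/1e-8, one optimiser state per sub-network) takes three sequential
steps:

1. **reconstruction** — encoder + decoder minimise mean squared error;
2. **discriminator** — binary cross-entropy separating fresh prior draws
   (target 1) from the current latent codes (target 0);
3. **generator** — the encoder is updated to make the discriminator assign
   its codes to the prior class (non-saturating loss).

All three share one decaying triangular cyclical learning rate: base 1e-4,
peak 5e-3, amplitude multiplied by γ = 0.98 after each full cycle, half-cycle
length defaulting to 4 epochs' worth of minibatches.  The first peak hits
the maximum exactly; the k-th peak is `base + γ^(k−1)·(max − base)`.

**Step-size balance.**  Because each phase has its own Adam state, Adam's
invariance to constant gradient rescaling means a loss weight multiplying
the adversarial gradients would have no effect; the balance knobs are
instead step-size multipliers on the generator (`adv_weight`) and
discriminator (`disc_weight`) updates.  With both at 1.0 the generator
over-reacts to a lagging discriminator and the latent means drift in a slow
limit cycle; a grid search at the defaults' scale found 0.5/0.5 the balanced
point, leaving per-dimension latent means within ±0.1, standard deviations
within [0.95, 1.07] of the prior's, a held-out probe unable to separate
latents from prior draws beyond AUC ≈ 0.57, and the trained discriminator's
mean outputs on prior versus encoded samples within 0.02 of each other —
with reconstruction loss indistinguishable from the unbalanced setting.
These are the defaults; both are configurable.

Weight initialisation is fan-in-scaled uniform from a seeded generator;
training, scoring and all bootstrap loops are deterministic given the seed
(per-iteration seeds derive from the master seed and iteration index, so
any single iteration can be replayed in isolation).

### Deviation inference

Per-region deviations are the *squared* residuals, so the observed
deviation is exactly their mean; a signed variant is exposed for inspecting
direction.  The bootstrap evaluation retrains the model per iteration on a
with-replacement resample of the reference cohort (size `n_ref` by default;
a `train_deficit` option reproduces protocols that draw slightly fewer),
then records per-group mean deviations, pairwise mean differences, AUCs of
each patient-group-vs-HC contrast (Mann–Whitney formulation, ties counted
½) and per-region Cliff's deltas.  Aggregation uses the percentile method
(linear-interpolation quantiles, 95% default); an effect is flagged
significant when its interval excludes zero.  Note what this interval
measures: variability of the *training* procedure (resampling + retraining),
not subject-sampling variability of the clinical cohorts, which are held
fixed — the same convention as the experiment it follows.

## Classifier baseline

The relevance vector machine is sparse Bayesian classification with a
linear kernel (`k(x, x') = ⟨x, x'⟩ / n_features`; the scaling makes the fit
exactly invariant to duplicated feature columns).  Fitting alternates a
Laplace (IRLS/Newton, with backtracking) approximation of the posterior
mode with MacKay evidence updates `αᵢ ← γᵢ/wᵢ²`, up to 500 outer iterations,
converging when the largest log-α change drops below 1e-3.  The raw MacKay
update oscillates with period 2 on collinear kernel columns, so the update
is damped by geometric interpolation in log space (factor 0.5).  Basis
functions are pruned when α exceeds 1e12 times the smallest α or an
absolute ceiling of 1e6 (posterior weight pinned within ~3e-3 of zero); the
bias is never pruned.  There is no margin parameter to tune.

The 0.632+ estimator resamples the pooled HC + patient subjects to the
pool's size, fits scaler + RVM on the sample, and computes resubstitution
and out-of-bag AUCs.  The no-information rate for an AUC is 0.5, the
relative overfitting rate `R = (AUC_resub − AUC_oob)/(AUC_resub − 0.5)` is
clipped to [0, 1] (with a degenerate denominator treated as R = 1 when the
out-of-bag AUC is worse, else 0), and `ω = 0.632/(1 − 0.368·R)` is capped
at 1 — ω is computed *per iteration*, inside the sum.  A draw whose sample
or out-of-bag set lacks a class is redrawn so the iteration count stays
fixed.  Cross-cohort generalization scores external cohorts with each
iteration's model, normalised by that model's own training scaler
(deployment logic).  Classifier-vs-normative comparisons pair the two
bootstrap schemes by iteration index and take the percentile interval of
the differences, truncating to the common iteration count when the two
schemes use different numbers of iterations.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular dataset.  Per subject and region,

    volume = baseline · (TIV/TIV_mean) · (1 + slope·(age−60) + sexoff·male)
             · (1 + effect) · exp(ε),   ε ~ N(0, noise_sd²).

- Ages are uniform integers on 47–73; sex is Bernoulli (male fraction 0.47);
  TIV is normal (mean 1.5·10⁶ mm³, SD 1.3·10⁵ mm³).
- Baselines: explicit plausible values for the 33 volumetric structures; a
  fixed, reproducible log-uniform spread over 2,000–22,000 mm³ for cortical
  parcels.  These are documented free parameters, not fitted values.
- Age slopes: −0.3%/yr cortical, −0.2%/yr subcortical grey, +2%/yr for
  CSF spaces.  Sex offset defaults to +1% for males after TIV correction.
- `noise_sd = 0.10`: multiplicative log-normal subject noise, the single
  between-subject dispersion knob.  The multiplicative form keeps volumes
  strictly positive by construction (no clipping or resampling is ever
  needed) and produces the right-skewed deviation distributions real
  morphometry shows.
- Disease stages multiply affected regions by `(1 + effect)`.  The default
  AD-analogue map touches 13 regions — hippocampus, entorhinal and
  parahippocampal cortex, amygdala (−20 to −25%), lateral ventricles and
  temporal horns (+40 to +50%), 3rd ventricle (+30%) — and scales linearly
  with a severity in [0, 1]; the graded cohort uses severities 0.3/0.6/1.0
  for the EMCI/LMCI/AD analogues.  A ground-truth manifest records the maps
  and affected indices.

What the generator does **not** emulate: scanner/site effects, spatial
covariance between regions, longitudinal change, diagnosis heterogeneity
(every AD-analogue subject expresses the same effect map), or non-linear
age trajectories.  Passing tests therefore demonstrate that the pipeline
recovers structure it is pointed at under its own assumptions — sensitivity
and calibration of the machinery — not clinical performance on real data.

## Problem sizes

Desk-scale defaults run the full pipeline in minutes on one CPU: reference
cohort n = 2,000, clinical groups of 150, B = 20 normative bootstrap
iterations, b = 50 classifier iterations, with the full 200-epoch training
schedule retained.  The null-calibration run uses a reference of 500.  The
full-scale experiment the defaults stand in for uses a reference of ~11,000
subjects and 1,000 iterations of both bootstraps; nothing in the code
limits those values, and `B`, `b`, cohort sizes and epochs are all
configurable.

## Known limitations

- The bootstrap intervals quantify training variability only (see above);
  with clinical cohorts held fixed, a fixed sampling fluctuation of a
  region can be flagged as significant more often than its nominal rate
  if the model ensemble is very stable.  The null-calibration check keeps
  this visible.
- The RVM's evidence maximisation is a local ascent; different damping or
  initial α can reach different (equivalent-quality) sparse solutions.
- The AAE equilibrium metrics were tuned at the desk-scale input
  distribution; markedly different feature scalings may need a different
  generator/discriminator balance.
- Latent dimension 20 and hidden widths 100 are fixed by design; the model
  is intentionally small and is not meant for voxel-level data.
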