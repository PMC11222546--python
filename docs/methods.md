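# Methods

`ecglyte` implements a complete methodology for predicting continuous blood
electrolyte concentrations from 12-lead ECGs and for quantifying the
uncertainty of those predictions. Because clinical ECG–lab archives are
access-restricted, the pipeline is exercised end-to-end on synthetic cohorts
whose electrolyte→waveform structure is known and controllable; every
component is nonetheless written for real data in the documented container
format.

## Synthetic cohorts

**Waveform model.** Each beat is a sum of Gaussian wavelets — P, Q, R, S and
T components with fixed per-lead amplitude maps over the 8 independent leads
(I, II, V1–V6) — repeated at RR intervals with a uniformly random start phase
and 3% relative RR jitter. Traces are in millivolt (the acquisition units of
clinical archives are device-dependent and unspecified; millivolt is the
package's documented convention). The generator is a statistical stand-in,
not a physiological simulator: no torso geometry, ionic currents, or rhythm
pathologies.

**Electrolyte effect.** Concentration `c` acts through two analytically
controlled channels that mirror the known clinical couplings: the T-wave
amplitude is scaled by `1 + a·(c − c_ref)` (potassium-like morphology
change, `a` dimensionless per unit concentration) and the S-to-T-onset
interval is shifted by `b·(c − c_ref)` seconds (calcium-like repolarization
lengthening). Profiles: strong `(a, b) = (0.5, 0.02)`, weak `(0.05, 0.002)`,
null `(0, 0)`. With all coefficients zero the waveform is provably
independent of concentration, which anchors the null-effect analyses. The
random beat phase and heart-rate variation make the concentration→trace map
translation-variant and nonlinear in the raw sample space — a convolutional
model can exploit it, whereas global-linear methods (PCA + linear
regression) cannot; this is deliberate, since it is the regime the clinical
comparison describes.

**Population structure.** Concentrations are Gaussian (truncated to a
positive physiological range) with the analyte's published marginal moments
(potassium 3.99 ± 0.50 mmol/l, calcium 2.29 ± 0.13, sodium 138.93 ± 3.82);
creatinine (90.55 ± 71.00 µmol/l) uses a moment-matched log-normal because a
Gaussian with sd ≈ 0.78·mean would be heavily truncated. Ages are
N(61.3, 19.6²) truncated to [18, 95]; 49.4% male; admissions uniform over
2009–2017 so the 2017-01-01 temporal cutoff is exercisable. The conditional
concentration sd is `sd·sqrt(1 + slope·z_age)` (clipped), which makes the
spread grow with age while keeping the marginal sd at the nominal value;
the default slope is 0.3.

**Timestamps.** Per encounter, ECG and lab times are drawn uniformly within
±90 minutes of an encounter time, so pairs both inside and outside the ±60
minute linking window occur. With probability 0.12 a patient has a second
encounter 30–500 days after admission, producing post-cutoff ECGs for
pre-cutoff patients (the leakage case the split logic must remove).

**Signal quality.** Noise comprises baseline wander (0.33 Hz), mains
interference (50 Hz default, configurable to 60), and white noise. Each
ECG's white-noise amplitude is additionally scaled by a lognormal factor
`exp(0.75·N(0,1))`: clinical archives mix clean and heavily disturbed
recordings, and this input-quality heterogeneity is what gives a
heteroscedastic model a learnable association between hard-to-read traces
and large residuals. Without it the variance head has no training signal
about input corruption and its behaviour under injected noise is arbitrary.
Lab values carry measurement noise around the patient's true concentration
(default sd = 0.1 of the marginal sd; optionally growing with the
standardized concentration for heteroscedastic-label experiments).

**What passing tests do not show.** The generator's effect channels are far
cleaner than real electrophysiology: recovery of the strong-effect cohort
demonstrates that the pipeline's mechanics are sound (losses, training,
splits, metrics), not that the architecture would reach any particular
accuracy on clinical data.

## Dataset construction

ECGs enter the dataset iff at least one lab value of the analyte lies within
a closed ±60 minute window of the acquisition time; the assigned target is
the median of that ECG's in-window labs, with an even count resolved as the
mean of the two central values. Splits are by patient: patients admitted on
or after the cutoff (default 2017-01-01) form the temporal test set
(subsampled to 10% of patients when more are available); the rest are
randomly partitioned 70/20 into development and random test, and the
development patients 90/10 into train/val (the dev-internal proportion is a
package choice; it is seeded and configurable). Post-cutoff ECGs of
non-temporal patients are removed. Training keeps all of a patient's ECGs
(a form of augmentation); validation and both test sets keep only each
patient's earliest ECG.

Traces are resampled (polyphase rational resampling) to a common rate,
high-pass filtered (order-4 Butterworth, 0.5 Hz, zero-phase), notch filtered
(IIR notch, zero-phase), and zero-padded at the end to a fixed length. The
filters run before padding so the pad stays exactly zero. Both filters use
even-reflection padding several time-constants long: with finite 8–10 s
records, the default short padding of zero-phase filtering leaves large
backward-pass transients at the trace ends. The notch quality factor
defaults to 10 (≈5 Hz band at 50 Hz): a Q=30 notch is too narrow to remove
the spectral leakage skirt of mains interference in a finite record,
leaving ~24% of a pure mains tone's RMS at the edges. Targets are z-scored
with train-set statistics (population-sd convention).

The full-scale configuration is 400 Hz × 4096 samples. All shipped analyses
and tests run a desk-scale profile — generation at 256 Hz for 8 s,
preprocessing to 128 Hz × 1024 samples — with a proportionally small
backbone; profile sizes are stated with each analysis and are package
choices, with every component parametric in them.

## Models

All deep formulations share a 1-D residual convolutional backbone (stem
convolution, then residual blocks `conv–ReLU–conv` with a 1×1-conv skip on
shape changes, global average pooling to a feature vector) implemented in
numpy with explicit reverse-mode gradients. Heads are linear maps on the
feature vector:

* **direct**: one output, MSE loss on z-scored targets;
* **gaussian**: mean and raw-variance heads, heteroscedastic Gaussian NLL;
  the variance passes through a softplus with floor 1e-6 (the positivity
  transform is a package choice);
* **classification**: k logits, cross-entropy on the discretized class;
* **ordinal**: k−1 threshold logits, elementwise binary cross-entropy on the
  cumulative encoding (threshold j = 1 iff class > j).

Training uses Adam (lr 1e-3), a fixed epoch budget (default 30), seeded
shuffling, and returns the epoch checkpoint with the lowest validation
loss. The default desk backbone has 2 residual blocks with channels
(16, 24, 32), kernel 9 and stage stride 4 (a 32-dimensional feature); the
documented full-scale profile has 4 blocks, channels up to 256 and kernel
17. Batch size defaults to 64 (128 in the shipped analyses). Exact
full-scale hyperparameters of the clinical setting are not fixed by the
methodology; all are config knobs.

Baselines: (1) PCA of the vectorized traces to 256 components (randomized
SVD, fitted on training traces only) followed by linear regression,
gradient boosting and random forest; (2) batch-wise linear regression and a
3-layer MLP on the raw flattened input trained under the identical protocol
as the deep models.

## Discretization

For k = 3 the interval bounds are μ ± 2σ of the training targets; for k > 3
the k−1 bounds are evenly spaced on [μ−2σ, μ+2σ] (maximal interior width
4σ/(k−2)). Intervals are left-open/right-closed except the first, so a
boundary value takes the lower class. k = 2 uses clinical hypo/hyper
thresholds (potassium 3.5/5.5, calcium 2.0/2.75, sodium 130/150 mmol/l) as
two separate one-vs-rest tasks with strict inequalities; creatinine, which
has no accepted pair here, falls back to μ ± 2σ. Ordinal decoding counts
thresholds with probability > 0.5 over the k−1 cumulative outputs — a
monotone, rank-consistent rule (a formulation summing over k outputs would
allow class k+1; the k−1-threshold form is the coherent reading).
Class-to-value back-mapping uses interval midpoints; the half-open edge
intervals are closed by the training min/max (alternatively μ ± 3σ via
config).

## Uncertainty

An ensemble of Gaussian models (default 5 members; the shipped desk-scale
analyses use 3) differing only in seed yields three per-example estimates,
all reported as variances on the concentration scale (z-scale variances are
multiplied by the squared target sd):

* **aleatoric Gaussian** — ensemble-average predicted variance σ²(x);
* **epistemic ensemble** — population variance of the predicted means;
* **epistemic Laplace** — for each member, a Gaussian posterior over the
  last layer of the mean head: Σ⁻¹ = H + αI with
  H = Σᵢ φᵢφᵢᵀ/σ²ᵢ the generalized Gauss–Newton curvature of the training
  NLL (exact Hessian for this linear-in-parameters layer), φ the feature map
  with bias and σ²ᵢ the member's predicted variances; the linearized
  predictive variance φ(x)ᵀΣφ(x) is averaged over members. The prior
  precision α is chosen by maximizing the Laplace marginal likelihood on a
  log grid (fixed values accepted); a singular curvature is jittered once
  (1e-8 of the mean diagonal) and otherwise raised.

Linearization (rather than posterior sampling) is the package's choice for
the Laplace predictive.

## Evaluation

Regression metrics are MSE, MAE, Pearson R and Spearman ρ (midranks for
ties); degenerate inputs yield NaN correlations with a warning. Stratified
reporting uses decade age bins (18–29 … 80+) and sex, with MAE on
sd-normalized targets plus the per-stratum target sd. For a k-class scheme
the ROC family comprises the k−1 cumulative events {class ≤ i}, scored by
cumulative class-probability mass (classification) or 1 − threshold
probability (ordinal); AUmROC is their arithmetic mean, and single-label
events are excluded as NaN. Sparsification reports the MAE of the retained
least-uncertain (1−f) fraction with stable tie-breaking; calibration is
central-interval Gaussian coverage versus nominal level.

Distribution-shift protocols: additive white Gaussian noise scaled to a
linear signal-to-noise power ratio (power measured over the non-padded
region, noise added only there so padding is preserved), and masking of
`round(p·samples)` samples per lead (one contiguous segment by default,
scattered samples optionally). The OOD table reports MAE of the
ensemble-mean prediction (with member sd) and the three uncertainties on
the sd scale.

## Numerical and design notes

* Seeding: every stochastic step (generation, initialization, shuffling,
  perturbation) is a pure function of an explicit integer seed; cohort
  regeneration is bit-identical, and model checkpoints reload with
  bit-identical predictions.
* The desk-scale study sizes were chosen so each property is statistically
  decidable: the null-effect comparison uses a cohort of ~12,000 ECGs
  because ordinary least squares on 256 PCA components inflates test MSE by
  the factor 1 + 256/n_train, which must be small against the ±10% band the
  variance argument is tested at; the discretization spectrum uses ~2,200
  patients so the rare μ±2σ tail classes (≈2.3% each) have enough training
  examples to be learnable at all, and its ROC families are measured on a
  ~3,200-example held-out simulated cohort because the split's own test set
  gives each tail event only a handful of positives (AUROC noise of several
  points, enough to flip qualitative comparisons).
* Ensemble disagreement shrinks with data volume through two mechanisms —
  member-to-member fit variability and validation-selection noise — both of
  which require the comparison to scale the whole development set (training
  and validation together) and to give both conditions a comparable
  optimization-step budget; subsetting only the training set while sharing a
  large validation set couples the members and suppresses the effect.
* Degenerate inputs: constant training targets raise rather than silently
  normalizing; ECGs without an in-window lab are dropped with a reported
  count; empty cohorts round-trip through the container.
* Known limitations: no signal-quality rejection or beat detection; the
  temporal test set on synthetic data measures only the split mechanics
  (there is no real temporal drift in the generator); calibration of the
  uncertainty estimates is reported, not enforced. The behaviour of AUmROC
  as k grows is scale-dependent: at clinical scale the extreme classes are
  learned from thousands of examples and finer discretization mainly adds
  harder interior events, while at desk scale (tens of tail examples) the
  k = 3 models learn the extreme classes poorly and coarse discretization
  is *not* easier — the corresponding test documents this expectation and
  currently fails at desk scale, by design rather than oversight.
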