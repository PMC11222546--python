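# ecglyte

Continuous electrolyte-concentration prediction from 12-lead ECGs, with
calibrated dataset construction and uncertainty quantification.

Blood electrolytes (potassium, calcium, sodium; creatinine treated
alongside) modulate cardiac electrophysiology and leave characteristic
fingerprints on the ECG — potassium chiefly in T-wave morphology, calcium in
the repolarization (QT) interval. Measuring them normally requires a blood
draw; an ECG-based estimate would enable monitoring in ambulances, telehealth
and remote settings. This package implements that methodology end-to-end for
researchers in clinical machine learning:

* a **synthetic cohort generator** with a known, controllable
  electrolyte→morphology forward model (Gaussian-wavelet beats over 8
  independent leads, concentration-dependent T-amplitude and
  repolarization-interval shifts, realistic demographics, timestamps and
  signal-quality variation), so every downstream claim is testable against
  ground truth;
* the **clinical dataset-construction rules**: ±60-minute ECG↔lab linking
  with median target assignment, first-ECG selection for evaluation sets,
  patient-level 70/10/20 random/temporal splits with a 2017-01-01 cutoff and
  post-cutoff leakage removal, 400 Hz / 4096-sample preprocessing (high-pass
  + notch, zero-padding);
* a **model spectrum** over a shared 1-D residual convolutional backbone:
  deep direct regression (MSE), heteroscedastic Gaussian regression
  (`p(y|x) = N(y; μ_θ(x), σ²_θ(x))` trained by NLL), k-class classification
  (cross-entropy over μ±2σ / evenly spaced intervals) and rank-consistent
  ordinal regression (k−1 cumulative thresholds, decoded as
  `ỹ = 1 + Σⱼ 1[p_j > 0.5]`), plus five traditional baselines (PCA-256 +
  linear/GBM/random forest; batch-wise linear and 3-layer MLP);
* **uncertainty estimation** from an ensemble of Gaussian models: aleatoric
  (mean predicted σ²), epistemic ensemble (variance of μ across members) and
  epistemic last-layer Laplace (`Σ⁻¹ = H + αI` with the Gauss–Newton
  curvature `H = Σ φφᵀ/σ²`, predictive variance `φ(x)ᵀΣφ(x)`);
* the **evaluation suite**: MSE/MAE/Pearson R/Spearman ρ, age/sex
  stratification, cumulative-event ROC families and AUmROC versus k, binary
  hypo/hyper AUROC, sparsification and calibration curves,
  uncertainty–error correlation, and SNR-noise / masking distribution-shift
  protocols.

The neural-network layer (convolutions, residual blocks, Adam, the four
losses) is a compact numpy implementation with explicit reverse-mode
gradients — small, dependency-light and exactly reproducible from a seed.

## Worked example

```python
from dataclasses import replace

from ecglyte.synthetic import ANALYTES, STRONG_EFFECT, sample_cohort
from ecglyte.preprocessing import assemble_datasets
from ecglyte.models import TINY_BACKBONE, TrainConfig, train_direct, predict
from ecglyte.evaluation import regression_metrics

cohort = sample_cohort(ANALYTES["potassium"], n_patients=700, seed=2,
                       effect=STRONG_EFFECT)
data = assemble_datasets(cohort, target_fs=128.0, target_len=1024, seed=2)
model = train_direct(data["train"], data["val"],
                     replace(TINY_BACKBONE, input_shape=(8, 1024)),
                     TrainConfig(epochs=30, seed=0))
test = data["random_test"]
print(regression_metrics(predict(model, test.X), test.y).to_dict())
```

prints (numbers from this exact run):

```
{'mse': 0.00731, 'mae': 0.0594, 'pearson_r': 0.9839, 'spearman_rho': 0.9861, 'n': 102}
```

The cohort's potassium-like analyte has marginal 3.99 ± 0.50 mmol/l, so a
mean predictor would score MSE ≈ 0.25; the residual network's MSE of 0.007
and Pearson R of 0.98 show it recovered the injected T-wave→concentration
relationship from the raw traces. On a null-effect cohort (the same
generator with the effect coefficients at zero) the same training run lands
at MSE ≈ the target variance — the signature that nothing was learnable —
and the five baselines behave the same way on both cohorts because the
random beat phase hides the amplitude signal from global-linear features.

The numbered scripts under `analysis/` run the full study at desk scale and
write tables under `results/`: cohort simulation (`01`), preprocessing and
linking (`02`), the deep-vs-baseline regression comparison (`03`), the
AUmROC-versus-k discretization spectrum (`04`), the uncertainty
decomposition with sparsification/calibration (`05`) and the
distribution-shift table (`06`). A thin CLI (`ecglyte simulate|preprocess|
run|spectrum`) wraps the same library calls.

## Documentation

`docs/methods.md` describes the generator's statistical model, every
dataset-construction rule, the model and uncertainty mathematics, the
numerical choices and the known limitations.
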