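"""Uncertainty decomposition of the Gaussian ensemble: sparsification,
calibration, and the correlation of each estimate with the squared error.

Trains an ensemble of heteroscedastic Gaussian models on a variable-quality
cohort, fits the last-layer Laplace posterior to each member's mean head,
and evaluates the three uncertainty estimates (aleatoric Gaussian, epistemic
ensemble, epistemic Laplace) on the random test set.
"""
import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ecglyte.evaluation import (
    calibration_curve,
    sparsification,
    uncertainty_error_correlation,
)
from ecglyte.models import TINY_BACKBONE, TrainConfig
from ecglyte.preprocessing import assemble_datasets
from ecglyte.synthetic import ANALYTES, NoiseSpec, STRONG_EFFECT, sample_cohort
from ecglyte.uncertainty import estimate_uncertainties, fit_laplace, train_ensemble
from dataclasses import replace


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--seed", type=int, default=6)
    ap.add_argument("--n-members", type=int, default=5)
    ap.add_argument("--epochs", type=int, default=20)
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = sample_cohort(ANALYTES["potassium"], 1000, seed=args.seed,
                           effect=STRONG_EFFECT,
                           noise=NoiseSpec(0.05, 0.02, 50.0, 0.1),
                           target_noise_sd=0.15)
    data = assemble_datasets(cohort, target_fs=128.0, target_len=1024,
                             val_fraction_of_dev=0.15, seed=args.seed)
    backbone = replace(TINY_BACKBONE, input_shape=(8, 1024))
    ens = train_ensemble(data["train"], data["val"], backbone,
                         TrainConfig(epochs=args.epochs, batch_size=128, seed=args.seed),
                         n_members=args.n_members, base_seed=args.seed + 100)
    posts = [fit_laplace(m, data["train"]) for m in ens.members]
    test = data["random_test"]
    est = estimate_uncertainties(ens, posts, test.X)
    abs_err = np.abs(est.mean_prediction - test.y)
    print(f"test MAE {abs_err.mean():.3f} over n={len(test)}")
    print("median variances: "
          f"aleatoric {np.median(est.aleatoric_gaussian):.4f}  "
          f"ensemble {np.median(est.epistemic_ensemble):.4f}  "
          f"laplace {np.median(est.epistemic_laplace):.4f}")

    fracs = np.arange(0.0, 0.95, 0.05)
    sp = {name: sparsification(abs_err, u, fracs).mae
          for name, u in (("aleatoric_gaussian", est.aleatoric_gaussian),
                          ("epistemic_ensemble", est.epistemic_ensemble),
                          ("epistemic_laplace", est.epistemic_laplace),
                          ("oracle", abs_err))}
    pd.DataFrame({"fraction_removed": fracs, **sp}).to_csv(
        out / "sparsification.csv", index=False)

    cal = calibration_curve(est.mean_prediction, est.total_variance, test.y)
    pd.DataFrame({"nominal": cal["nominal"], "empirical": cal["empirical"]}).to_csv(
        out / "calibration.csv", index=False)

    corr = uncertainty_error_correlation(
        {"aleatoric_gaussian": est.aleatoric_gaussian,
         "epistemic_ensemble": est.epistemic_ensemble,
         "epistemic_laplace": est.epistemic_laplace},
        abs_err**2,
        combinations=[("aleatoric_gaussian", "epistemic_ensemble")],
    )
    pd.DataFrame([corr]).to_csv(out / "uncertainty_error_correlation.csv", index=False)
    print("correlation with squared error:",
          {k: round(v, 3) for k, v in corr.items()})
    print(f"\nwrote sparsification.csv, calibration.csv, "
          f"uncertainty_error_correlation.csv under {out}")


if __name__ == "__main__":
    main()
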