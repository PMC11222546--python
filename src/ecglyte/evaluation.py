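"""Metrics, stratifications, ROC families, uncertainty diagnostics and OOD protocols.

Conventions: Spearman uses midranks for ties; correlations on degenerate
(zero-variance) inputs are reported as NaN with a warning rather than raising;
the cumulative ROC family for a k-class scheme consists of the k−1 events
{true class ≤ i}, and the AUmROC is the arithmetic mean of their AUROCs.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .discretization import BinaryTaskPair

__all__ = [
    "MetricsReport",
    "ROCFamily",
    "SparsificationResult",
    "regression_metrics",
    "stratified_metrics",
    "cumulative_roc",
    "binary_auroc_pair",
    "sparsification",
    "calibration_curve",
    "uncertainty_error_correlation",
    "perturb_noise",
    "perturb_mask",
    "ood_report",
    "DEFAULT_AGE_BINS",
]

#: Decade age strata: 18–29, 30–39, …, 70–79, 80+.
DEFAULT_AGE_BINS: tuple = (18, 30, 40, 50, 60, 70, 80, np.inf)


@dataclass
class MetricsReport:
    mse: float
    mae: float
    pearson_r: float
    spearman_rho: float
    n: int

    def to_dict(self) -> dict:
        return {
            "mse": self.mse,
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "n": self.n,
        }


def _safe_corr(preds: np.ndarray, targets: np.ndarray, method: str) -> float:
    if preds.std() == 0 or targets.std() == 0:
        warnings.warn(f"{method} correlation undefined for constant input; reporting NaN")
        return float("nan")
    if method == "pearson":
        return float(stats.pearsonr(preds, targets).statistic)
    return float(stats.spearmanr(preds, targets).statistic)


def regression_metrics(preds, targets) -> MetricsReport:
    """MSE, MAE, Pearson R and Spearman ρ of continuous predictions."""
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if preds.shape != targets.shape:
        raise ValueError("preds and targets must have the same shape")
    err = preds - targets
    return MetricsReport(
        mse=float(np.mean(err**2)),
        mae=float(np.mean(np.abs(err))),
        pearson_r=_safe_corr(preds, targets, "pearson"),
        spearman_rho=_safe_corr(preds, targets, "spearman"),
        n=len(preds),
    )


def stratified_metrics(
    preds, targets, ages, sexes, age_bins: tuple = DEFAULT_AGE_BINS
) -> dict:
    """Per-stratum normalized-target MAE and target sd, by age decade and sex.

    Targets (and predictions) are divided by the overall target sd so MAE
    values are comparable across analytes; each stratum also reports the sd
    of its raw targets.
    """
    preds = np.asarray(preds, dtype=float)
    targets = np.asarray(targets, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sexes = np.asarray(sexes)
    scale = targets.std()
    if scale == 0:
        raise ValueError("degenerate targets")

    def stratum(mask: np.ndarray) -> dict:
        return {
            "n": int(mask.sum()),
            "mae_normalized": float(np.mean(np.abs(preds[mask] - targets[mask])) / scale)
            if mask.any()
            else float("nan"),
            "target_sd": float(targets[mask].std()) if mask.any() else float("nan"),
        }

    by_age = {}
    for lo, hi in zip(age_bins[:-1], age_bins[1:]):
        label = f"{int(lo)}-{int(hi) - 1}" if np.isfinite(hi) else f"{int(lo)}+"
        by_age[label] = stratum((ages >= lo) & (ages < hi))
    by_sex = {s: stratum(sexes == s) for s in ("male", "female")}
    return {"age": by_age, "sex": by_sex}


@dataclass
class ROCFamily:
    """The k−1 cumulative-event ROC curves of a k-class scheme."""

    k: int
    aurocs: list
    curves: list = field(default_factory=list)  # (fpr, tpr) pairs

    @property
    def aumroc(self) -> float:
        return float(np.nanmean(self.aurocs))


def _binary_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


def cumulative_roc(probs, true_classes, k: int, kind: str) -> ROCFamily:
    """ROC family over the events {true class ≤ i}, i = 1..k−1.

    ``kind="classification"``: ``probs`` is (n, k) class probabilities and
    the event score is the cumulative mass on classes ≤ i.
    ``kind="ordinal"``: ``probs`` is (n, k−1) threshold probabilities
    p(class > i) and the event score is 1 − p(class > i). Events with only
    one observed label yield NaN AUROC and are excluded from the mean.
    """
    from sklearn.metrics import roc_curve

    probs = np.asarray(probs, dtype=float)
    classes = np.asarray(true_classes, dtype=int)
    if kind == "classification":
        if probs.shape[1] != k:
            raise ValueError("classification probs must have k columns")
        cum = np.cumsum(probs, axis=1)
        scores = [cum[:, i - 1] for i in range(1, k)]
    elif kind == "ordinal":
        if probs.shape[1] != k - 1:
            raise ValueError("ordinal probs must have k-1 columns")
        scores = [1.0 - probs[:, i - 1] for i in range(1, k)]
    else:
        raise ValueError(f"unknown kind {kind!r}")

    aurocs, curves = [], []
    for i, s in enumerate(scores, start=1):
        labels = (classes <= i).astype(int)
        aurocs.append(_binary_auroc(s, labels))
        if len(np.unique(labels)) == 2:
            fpr, tpr, _ = roc_curve(labels, s)
            curves.append((fpr, tpr))
        else:
            curves.append((np.array([]), np.array([])))
    return ROCFamily(k=k, aurocs=aurocs, curves=curves)


def binary_auroc_pair(
    hypo_scores, hyper_scores, targets, pair: BinaryTaskPair
) -> dict:
    """AUROC of the hypo and hyper one-vs-rest tasks, plus their average.

    ``hypo_scores``/``hyper_scores`` are continuous risk scores for the
    respective abnormality (higher = more likely abnormal).
    """
    y = np.asarray(targets, dtype=float)
    hypo = _binary_auroc(np.asarray(hypo_scores, dtype=float), pair.hypo_labels(y))
    hyper = _binary_auroc(np.asarray(hyper_scores, dtype=float), pair.hyper_labels(y))
    return {"hypo_auroc": hypo, "hyper_auroc": hyper,
            "average": float(np.nanmean([hypo, hyper]))}


@dataclass
class SparsificationResult:
    fractions: np.ndarray
    mae: np.ndarray  # MAE of the retained (least-uncertain) subset


def sparsification(
    abs_errors, uncertainties, fractions=None
) -> SparsificationResult:
    """Retained-subset MAE after removing the most uncertain fraction.

    For each removal fraction f, the (1−f) share of examples with the
    smallest uncertainty is kept (ties broken by stable input order) and its
    MAE reported; f = 0 reproduces the full-set MAE.
    """
    err = np.asarray(abs_errors, dtype=float)
    unc = np.asarray(uncertainties, dtype=float)
    if fractions is None:
        fractions = np.arange(0.0, 1.0, 0.05)
    fractions = np.asarray(fractions, dtype=float)
    order = np.argsort(unc, kind="stable")
    sorted_err = err[order]
    mae = np.array(
        [
            sorted_err[: max(1, int(round((1.0 - f) * len(err))))].mean()
            for f in fractions
        ]
    )
    return SparsificationResult(fractions=fractions, mae=mae)


def calibration_curve(mean, total_variance, targets, nominal_levels=None) -> dict:
    """Empirical coverage of central Gaussian prediction intervals.

    For each nominal level q the fraction of targets inside
    μ ± z_{(1+q)/2} σ is reported.
    """
    mu = np.asarray(mean, dtype=float)
    sd = np.sqrt(np.asarray(total_variance, dtype=float))
    y = np.asarray(targets, dtype=float)
    if nominal_levels is None:
        nominal_levels = np.arange(0.1, 1.0, 0.1)
    nominal_levels = np.asarray(nominal_levels, dtype=float)
    coverage = []
    for q in nominal_levels:
        z = stats.norm.ppf((1.0 + q) / 2.0)
        coverage.append(float(np.mean(np.abs(y - mu) <= z * sd)))
    return {"nominal": nominal_levels, "empirical": np.array(coverage)}


def uncertainty_error_correlation(
    uncertainties: dict, squared_errors, combinations=()
) -> dict:
    """Pearson correlation of each uncertainty (and summed combinations) with
    the per-example squared error."""
    se = np.asarray(squared_errors, dtype=float)
    out = {}
    items = {name: np.asarray(u, dtype=float) for name, u in uncertainties.items()}
    for name, u in items.items():
        out[name] = _safe_corr(u, se, "pearson")
    for combo in combinations:
        u = np.sum([items[name] for name in combo], axis=0)
        out["+".join(combo)] = _safe_corr(u, se, "pearson")
    return out


# ----------------------------------------------------------------------------
# OOD perturbations
# ----------------------------------------------------------------------------

def _valid_length(trace: np.ndarray) -> int:
    """Length excluding the trailing all-zero padding (at least 1)."""
    nz = np.nonzero(np.any(trace != 0, axis=0))[0]
    return int(nz[-1]) + 1 if nz.size else trace.shape[1]


def perturb_noise(X, snr: float, seed: int = 0) -> np.ndarray:
    """Additive white Gaussian noise at a fixed signal-to-noise power ratio.

    ``snr`` is a linear power ratio. Signal power is the mean square over all
    leads and the non-padded samples of each trace; noise with variance
    power/snr is added to that region only, so the zero-padding tail is
    preserved and the realized ratio matches by construction.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    X = np.asarray(X)
    rng = np.random.default_rng(seed)
    out = X.astype(np.float32).copy()
    for i in range(len(out)):
        n_valid = _valid_length(out[i])
        power = float(np.mean(out[i, :, :n_valid].astype(float) ** 2))
        sd = np.sqrt(power / snr)
        out[i, :, :n_valid] += (
            sd * rng.standard_normal((out.shape[1], n_valid))
        ).astype(np.float32)
    return out


def perturb_mask(
    X, proportion: float, seed: int = 0, mode: str = "contiguous"
) -> np.ndarray:
    """Zero out ``round(proportion * samples)`` samples per lead of each trace.

    ``contiguous`` masks one random segment per trace (the same across its
    leads); ``scattered`` masks random individual samples.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    X = np.asarray(X)
    out = X.astype(np.float32).copy()
    if proportion == 0.0:
        return out
    rng = np.random.default_rng(seed)
    n = out.shape[2]
    n_mask = int(round(proportion * n))
    for i in range(len(out)):
        if mode == "contiguous":
            start = int(rng.integers(0, n - n_mask + 1))
            out[i, :, start : start + n_mask] = 0.0
        elif mode == "scattered":
            idx = rng.choice(n, size=n_mask, replace=False)
            out[i, :, idx] = 0.0
        else:
            raise ValueError(f"unknown mask mode {mode!r}")
    return out


def ood_report(ensemble, posteriors, conditions: dict, targets) -> dict:
    """MAE and the three uncertainty summaries per perturbation condition.

    ``conditions`` maps condition name → perturbed trace array (same example
    order as ``targets``). MAE is reported for the ensemble-mean prediction
    with the sd of per-member MAEs; uncertainties are reported on the sd
    scale (square roots of the variance estimates), averaged over examples.
    """
    from .uncertainty import (
        _member_predictions,
        epistemic_laplace,
    )

    y = np.asarray(targets, dtype=float)
    report = {}
    for name, X in conditions.items():
        mus, variances = _member_predictions(ensemble, X)
        member_mae = np.mean(np.abs(mus - y[None, :]), axis=1)
        lap = epistemic_laplace(ensemble, posteriors, X)
        report[name] = {
            "mae": float(np.mean(np.abs(mus.mean(axis=0) - y))),
            "mae_member_sd": float(member_mae.std()),
            "aleatoric_gaussian": float(np.mean(np.sqrt(variances.mean(axis=0)))),
            "epistemic_ensemble": float(np.mean(np.sqrt(mus.var(axis=0)))),
            "epistemic_laplace": float(np.mean(np.sqrt(lap))),
        }
    return report
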