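"""Uncertainty estimation for the Gaussian ensemble.

Three estimators, all reported as variances on the de-normalized
(concentration) scale:

* **aleatoric Gaussian** — the ensemble-average of the per-example predicted
  variance σ²_θ(x); irreducible data noise.
* **epistemic ensemble** — the population variance of the predicted mean
  μ_θ(x) across ensemble members; disagreement between independently seeded
  training runs.
* **epistemic Laplace** — a Gaussian posterior over the last layer of the
  mean head, N(θ_MAP, Σ) with Σ⁻¹ the curvature of the training objective at
  the trained weights (generalized Gauss–Newton of the Gaussian NLL, which
  for a linear-in-parameters last layer is the exact Hessian) plus an
  isotropic prior precision. The linearized predictive variance is
  φ(x)ᵀ Σ φ(x) with φ the last-layer feature map (with bias), averaged over
  members.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import ModelState, TrainConfig, BackboneConfig, predict_gaussian, train_gaussian
from .preprocessing import ArrayDataset

__all__ = [
    "Ensemble",
    "LaplacePosterior",
    "UncertaintyEstimates",
    "train_ensemble",
    "ensemble_mean_prediction",
    "aleatoric_gaussian",
    "epistemic_ensemble",
    "fit_laplace",
    "epistemic_laplace",
    "estimate_uncertainties",
]


@dataclass
class Ensemble:
    """Gaussian-head models trained identically except for the seed."""

    members: list

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("ensemble needs at least one member")
        for m in self.members:
            if m.task != "gaussian":
                raise ValueError("ensemble members must have gaussian heads")

    @property
    def n_members(self) -> int:
        return len(self.members)


def train_ensemble(
    train: ArrayDataset,
    val: ArrayDataset,
    backbone: BackboneConfig,
    cfg: TrainConfig,
    n_members: int = 5,
    base_seed: int = 0,
) -> Ensemble:
    """Train ``n_members`` Gaussian models differing only in seed."""
    members = [
        train_gaussian(train, val, backbone, replace(cfg, seed=base_seed + i))
        for i in range(n_members)
    ]
    return Ensemble(members)


def _member_predictions(ensemble: Ensemble, X):
    mus, variances = [], []
    for m in ensemble.members:
        mu, var = predict_gaussian(m, X)
        mus.append(mu)
        variances.append(var)
    return np.stack(mus), np.stack(variances)  # (members, n)


def ensemble_mean_prediction(ensemble: Ensemble, X) -> np.ndarray:
    mus, _ = _member_predictions(ensemble, X)
    return mus.mean(axis=0)


def aleatoric_gaussian(ensemble: Ensemble, X) -> np.ndarray:
    """Average predicted variance σ²_θ(x) over members (concentration² scale)."""
    _, variances = _member_predictions(ensemble, X)
    return variances.mean(axis=0)


def epistemic_ensemble(ensemble: Ensemble, X) -> np.ndarray:
    """Population variance of the predicted mean across members."""
    mus, _ = _member_predictions(ensemble, X)
    return mus.var(axis=0)


@dataclass
class LaplacePosterior:
    """Last-layer Gaussian posterior of one member's mean head."""

    theta_map: np.ndarray  # (d+1,) mean-head weights, bias last
    cov: np.ndarray  # (d+1, d+1) SPD
    prior_precision: float

    def __post_init__(self) -> None:
        # SPD check; raises LinAlgError if the curvature is singular
        np.linalg.cholesky(self.cov)


def _features_with_bias(member: ModelState, X) -> np.ndarray:
    net = member.network()
    chunks = [net.features(X[i : i + 256]) for i in range(0, len(X), 256)]
    phi = np.concatenate(chunks).astype(float) if chunks else np.zeros((0, member.backbone.feature_dim))
    return np.hstack([phi, np.ones((len(phi), 1))])


def _log_marglik(alpha: float, eigs: np.ndarray, theta: np.ndarray) -> float:
    d = theta.size
    return (
        0.5 * d * np.log(alpha)
        - 0.5 * alpha * float(theta @ theta)
        - 0.5 * float(np.sum(np.log(eigs + alpha)))
    )


def fit_laplace(
    member: ModelState,
    train: ArrayDataset,
    prior_precision: float | str = "marglik",
    observation_variance: float | None = None,
) -> LaplacePosterior:
    """Fit the last-layer Laplace approximation on the training data.

    The curvature is the generalized Gauss–Newton of the Gaussian NLL with
    respect to the mean-head parameters, ``H = Σ_i φ_i φ_iᵀ / σ²_i``, with
    σ²_i the member's predicted (z-scale) variance — or a fixed
    ``observation_variance`` when given. ``Σ⁻¹ = H + α I`` with the prior
    precision α either fixed or optimized by the Laplace marginal likelihood
    on a log grid.
    """
    phi = _features_with_bias(member, train.X)
    if observation_variance is not None:
        sigma2 = np.full(len(phi), float(observation_variance))
    else:
        _, var = predict_gaussian(member, train.X)
        sigma2 = var / member.normalization.sd**2  # back to the z scale
    H = (phi / sigma2[:, None]).T @ phi

    net = member.network()
    head = net.heads[0]
    theta = np.concatenate([head.W.ravel(), head.b]).astype(float)

    if prior_precision == "marglik":
        eigs = np.linalg.eigvalsh(H)
        grid = np.logspace(-4, 4, 81)
        alpha = float(grid[np.argmax([_log_marglik(a, eigs, theta) for a in grid])])
    else:
        alpha = float(prior_precision)
        if alpha <= 0:
            raise ValueError("prior precision must be positive")

    precision = H + alpha * np.eye(H.shape[0])
    try:
        cov = np.linalg.inv(precision)
        return LaplacePosterior(theta, (cov + cov.T) / 2.0, alpha)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * np.trace(precision) / precision.shape[0]
        cov = np.linalg.inv(precision + jitter * np.eye(precision.shape[0]))
        return LaplacePosterior(theta, (cov + cov.T) / 2.0, alpha)


def laplace_predictive_variance(
    member: ModelState, posterior: LaplacePosterior, X
) -> np.ndarray:
    """Linearized predictive variance φᵀ Σ φ on the concentration scale."""
    phi = _features_with_bias(member, X)
    v = np.einsum("nd,de,ne->n", phi, posterior.cov, phi)
    return np.maximum(v, 0.0) * member.normalization.sd**2


def epistemic_laplace(
    ensemble: Ensemble, posteriors: list[LaplacePosterior], X
) -> np.ndarray:
    """Average last-layer Laplace predictive variance over members."""
    if len(posteriors) != ensemble.n_members:
        raise ValueError("need one posterior per ensemble member")
    out = np.zeros(len(X))
    for member, post in zip(ensemble.members, posteriors):
        out += laplace_predictive_variance(member, post, X)
    return out / ensemble.n_members


@dataclass
class UncertaintyEstimates:
    """Per-example uncertainty decomposition (variances, concentration² scale)."""

    mean_prediction: np.ndarray
    aleatoric_gaussian: np.ndarray
    epistemic_ensemble: np.ndarray
    epistemic_laplace: np.ndarray

    def __post_init__(self) -> None:
        for name in ("aleatoric_gaussian", "epistemic_ensemble", "epistemic_laplace"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} contains negative variances")

    @property
    def total_variance(self) -> np.ndarray:
        return self.aleatoric_gaussian + self.epistemic_ensemble


def estimate_uncertainties(
    ensemble: Ensemble, posteriors: list[LaplacePosterior], X
) -> UncertaintyEstimates:
    mus, variances = _member_predictions(ensemble, X)
    return UncertaintyEstimates(
        mean_prediction=mus.mean(axis=0),
        aleatoric_gaussian=variances.mean(axis=0),
        epistemic_ensemble=mus.var(axis=0),
        epistemic_laplace=epistemic_laplace(ensemble, posteriors, X),
    )
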