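"""Interval schemes, class encoding/decoding and class-to-continuous mapping.

A regression target range is discretized into ``k`` ordered intervals. For
``k = 3`` the two bounds sit at μ ± 2σ of the training targets; for ``k > 3``
the ``k − 1`` bounds are evenly spaced on [μ − 2σ, μ + 2σ] inclusive of the
two extremes (so the maximal interior width shrinks as 4σ/(k − 2)). The
binary (k = 2) case is handled separately by clinical hypo/hyper thresholds.

Intervals are left-open/right-closed except the first: a value exactly on a
bound belongs to the lower class. Ordinal (rank-consistent) models use
``k − 1`` cumulative thresholds: binary target ``j`` is 1 iff the class
exceeds ``j``, and decoding counts thresholds whose predicted probability
exceeds 0.5 — a monotone map, so elementwise-larger probabilities never
decrease the decoded class.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import AnalyteSpec

__all__ = [
    "IntervalScheme",
    "BinaryTaskPair",
    "DegenerateTargetsError",
    "build_scheme",
    "build_binary_tasks",
    "assign_class",
    "ordinal_encode",
    "ordinal_decode",
    "class_to_value",
]


class DegenerateTargetsError(ValueError):
    """Raised when training targets have zero spread."""


@dataclass(frozen=True)
class IntervalScheme:
    """An ordered k-class discretization. Classes are 1..k."""

    k: int
    bounds: tuple  # k-1 strictly increasing concentrations
    representative_values: tuple  # k concentrations, one per class
    construction: str = "mu_2sigma"

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if len(b) != self.k - 1:
            raise ValueError("need exactly k-1 bounds")
        if np.any(np.diff(b) <= 0):
            raise ValueError("bounds must be strictly increasing")
        r = np.asarray(self.representative_values, dtype=float)
        if len(r) != self.k:
            raise ValueError("need exactly k representative values")
        for i in range(1, self.k - 1):  # interior classes
            if not b[i - 1] < r[i] < b[i]:
                raise ValueError(
                    f"representative of class {i + 1} outside its interval"
                )

    def to_json_dict(self) -> dict:
        return {
            "k": self.k,
            "bounds": list(self.bounds),
            "representative_values": list(self.representative_values),
            "construction": self.construction,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "IntervalScheme":
        return cls(
            d["k"],
            tuple(d["bounds"]),
            tuple(d["representative_values"]),
            d.get("construction", "mu_2sigma"),
        )


@dataclass(frozen=True)
class BinaryTaskPair:
    """Two one-vs-rest tasks: hypo (y < hypo_bound) and hyper (y > hyper_bound)."""

    hypo_bound: float
    hyper_bound: float

    def __post_init__(self) -> None:
        if not self.hypo_bound < self.hyper_bound:
            raise ValueError("hypo bound must be below hyper bound")

    def hypo_labels(self, y) -> np.ndarray:
        """1 iff the value is abnormally low (strictly below the bound)."""
        return (np.asarray(y, dtype=float) < self.hypo_bound).astype(int)

    def hyper_labels(self, y) -> np.ndarray:
        """1 iff the value is abnormally high (strictly above the bound)."""
        return (np.asarray(y, dtype=float) > self.hyper_bound).astype(int)


def build_scheme(
    k: int,
    train_targets,
    edge_rule: str = "train_minmax",
) -> IntervalScheme:
    """Build the μ±2σ / evenly-spaced interval scheme from training targets.

    ``k = 3`` puts the two bounds at μ ± 2σ; larger ``k`` spaces the ``k−1``
    bounds uniformly over [μ−2σ, μ+2σ]. Interior representatives are interval
    midpoints; the half-open edge intervals are bounded for their midpoint by
    the training min/max (``edge_rule="train_minmax"``) or by μ±3σ
    (``edge_rule="mu_3sigma"``).
    """
    if k < 3:
        raise ValueError("build_scheme handles k >= 3; use build_binary_tasks for k=2")
    y = np.asarray(train_targets, dtype=float)
    mu, sigma = float(y.mean()), float(y.std())
    if sigma == 0:
        raise DegenerateTargetsError("training targets have zero sd")
    bounds = np.linspace(mu - 2 * sigma, mu + 2 * sigma, k - 1)

    if edge_rule == "train_minmax":
        lo_edge, hi_edge = float(y.min()), float(y.max())
    elif edge_rule == "mu_3sigma":
        lo_edge, hi_edge = mu - 3 * sigma, mu + 3 * sigma
    else:
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    lo_edge = min(lo_edge, bounds[0] - sigma * 1e-6)
    hi_edge = max(hi_edge, bounds[-1] + sigma * 1e-6)

    reps = [(lo_edge + bounds[0]) / 2.0]
    reps += [(bounds[i] + bounds[i + 1]) / 2.0 for i in range(k - 2)]
    reps += [(bounds[-1] + hi_edge) / 2.0]
    return IntervalScheme(k, tuple(bounds), tuple(reps), construction="mu_2sigma")


def build_binary_tasks(
    analyte: AnalyteSpec,
    train_targets=None,
    use_clinical_bounds: bool = True,
) -> BinaryTaskPair:
    """Hypo/hyper binary tasks from the analyte's clinical thresholds.

    For analytes without accepted clinical thresholds (creatinine-like), or
    with ``use_clinical_bounds=False``, the bounds fall back to μ ± 2σ of the
    training targets.
    """
    if use_clinical_bounds and analyte.name != "creatinine":
        return BinaryTaskPair(analyte.hypo_bound, analyte.hyper_bound)
    if train_targets is None:
        raise ValueError("μ±2σ fallback needs training targets")
    y = np.asarray(train_targets, dtype=float)
    mu, sigma = float(y.mean()), float(y.std())
    if sigma == 0:
        raise DegenerateTargetsError("training targets have zero sd")
    return BinaryTaskPair(mu - 2 * sigma, mu + 2 * sigma)


def assign_class(y, scheme: IntervalScheme) -> np.ndarray:
    """Class in 1..k: one plus the number of bounds strictly below y."""
    y = np.atleast_1d(np.asarray(y, dtype=float))
    bounds = np.asarray(scheme.bounds, dtype=float)
    return 1 + (y[:, None] > bounds[None, :]).sum(axis=1)


def ordinal_encode(classes, k: int) -> np.ndarray:
    """Cumulative-threshold encoding: target j is 1 iff class > j.

    Returns an ``(n, k-1)`` 0/1 array; class 1 maps to all zeros, class k to
    all ones.
    """
    c = np.atleast_1d(np.asarray(classes, dtype=int))
    if np.any((c < 1) | (c > k)):
        raise ValueError("classes must lie in 1..k")
    j = np.arange(1, k)
    return (c[:, None] > j[None, :]).astype(float)


def ordinal_decode(threshold_probs) -> np.ndarray:
    """Class = 1 + number of thresholds with probability > 0.5.

    ``threshold_probs`` is ``(n, k-1)``; the count over the k−1 cumulative
    thresholds yields a class in 1..k.
    """
    p = np.atleast_2d(np.asarray(threshold_probs, dtype=float))
    return 1 + (p > 0.5).sum(axis=1)


def class_to_value(classes, scheme: IntervalScheme) -> np.ndarray:
    """Map predicted classes back to concentrations (interval representatives)."""
    c = np.atleast_1d(np.asarray(classes, dtype=int))
    if np.any((c < 1) | (c > scheme.k)):
        raise ValueError("classes must lie in 1..k")
    reps = np.asarray(scheme.representative_values, dtype=float)
    return reps[c - 1]
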