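"""Beta-distribution primitives and constraint machinery for the mixture fit.

Scaled binding-affinity scores live in the open unit interval, so both mixture
components are two-parameter beta distributions.  Shape parameters are
estimated throughout by Pearson's method of moments — inverting the closed-form
mean/variance relations

    alpha = ((1 - mu) / var - 1 / mu) * mu**2
    beta  = alpha * (1 / mu - 1)

rather than by maximum likelihood.  This module also provides the admissible
parameter ranges ("constraints") that the EM loop projects estimates into: the
false component may be restricted to an envelope computed from decoy score
samples, and the true component to a +/-25% band around an initial estimate
when the input looks like pure decoys.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "BetaParams",
    "ConstraintRanges",
    "DegenerateMomentsError",
    "beta_pdf",
    "beta_logpdf",
    "beta_cdf",
    "mom_estimate",
    "weighted_moments",
    "constraints_from_samples",
    "project_into_range",
    "ranges_around",
]


class DegenerateMomentsError(ValueError):
    """Raised when (mean, variance) cannot come from any beta distribution."""


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a beta distribution; both must be positive."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and np.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and np.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def variance(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))

    def as_tuple(self) -> tuple[float, float]:
        return (self.alpha, self.beta)


def _check_open_unit(x: np.ndarray | float, name: str = "x") -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"{name} must lie strictly inside (0, 1)")
    return arr


def beta_pdf(x: np.ndarray | float, params: BetaParams) -> np.ndarray | float:
    """Beta density f(x; a, b) = G(a+b)/(G(a)G(b)) x^(a-1) (1-x)^(b-1).

    Evaluated in log space internally for numerical stability.  ``x`` must be
    strictly inside (0, 1); endpoint densities are undefined or infinite for
    some shapes and are rejected rather than guessed at.
    """
    arr = _check_open_unit(x)
    out = np.exp(stats.beta.logpdf(arr, params.alpha, params.beta))
    return float(out) if np.isscalar(x) else out


def beta_logpdf(x: np.ndarray | float, params: BetaParams) -> np.ndarray | float:
    arr = _check_open_unit(x)
    out = stats.beta.logpdf(arr, params.alpha, params.beta)
    return float(out) if np.isscalar(x) else out


def beta_cdf(x: np.ndarray | float, params: BetaParams) -> np.ndarray | float:
    """Regularized incomplete beta function I_x(a, b); defined on [0, 1]."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("x must lie in [0, 1]")
    out = stats.beta.cdf(arr, params.alpha, params.beta)
    return float(out) if np.isscalar(x) else out


def mom_estimate(mean: float, variance: float) -> BetaParams:
    """Method-of-moments inversion of beta mean/variance to (alpha, beta).

    Requires 0 < mean < 1 and 0 < variance < mean * (1 - mean); outside that
    region no beta distribution matches the moments and
    :class:`DegenerateMomentsError` is raised (the caller decides any clamping
    policy).
    """
    if not (0.0 < mean < 1.0):
        raise DegenerateMomentsError(f"mean must be in (0, 1), got {mean}")
    bound = mean * (1.0 - mean)
    if not (0.0 < variance < bound):
        raise DegenerateMomentsError(
            f"variance must be in (0, mean*(1-mean)) = (0, {bound:.6g}), got {variance}"
        )
    alpha = ((1.0 - mean) / variance - 1.0 / mean) * mean * mean
    beta = alpha * (1.0 / mean - 1.0)
    return BetaParams(alpha=alpha, beta=beta)


def weighted_moments(
    xs: Sequence[float] | np.ndarray, weights: Sequence[float] | np.ndarray
) -> tuple[float, float]:
    """Weighted mean and (biased) weighted variance of ``xs``.

    mu = sum(w x) / sum(w);  var = sum(w (x - mu)^2) / sum(w).
    """
    x = np.asarray(xs, dtype=float)
    w = np.asarray(weights, dtype=float)
    if x.shape != w.shape or x.ndim != 1 or x.size < 1:
        raise ValueError("xs and weights must be equal-length 1-d sequences")
    if np.any(w < 0.0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0.0:
        raise ValueError("zero weight sum: component is empty")
    mu = float(np.dot(w, x) / total)
    var = float(np.dot(w, (x - mu) ** 2) / total)
    return mu, var


@dataclass
class ConstraintRanges:
    """Admissible intervals for (alpha, beta), applied by projection.

    Serializable to a small JSON sidecar so users can precompute
    allele-specific ranges from their own decoy prediction runs.
    """

    alpha_interval: tuple[float, float]
    beta_interval: tuple[float, float]
    component: str = "false_component"

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("alpha_interval", self.alpha_interval),
            ("beta_interval", self.beta_interval),
        ):
            if not (0.0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < low <= high, got ({lo}, {hi})")
        if self.component not in ("true_component", "false_component"):
            raise ValueError(f"unknown component {self.component!r}")

    def to_dict(self) -> dict:
        return {
            "alpha_interval": list(self.alpha_interval),
            "beta_interval": list(self.beta_interval),
            "component": self.component,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConstraintRanges":
        return cls(
            alpha_interval=tuple(d["alpha_interval"]),
            beta_interval=tuple(d["beta_interval"]),
            component=d.get("component", "false_component"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "ConstraintRanges":
        return cls.from_dict(json.loads(Path(path).read_text()))


def constraints_from_samples(
    sample_sets: Iterable[Sequence[float] | np.ndarray],
    component: str = "false_component",
    min_size: int = 30,
) -> ConstraintRanges:
    """Envelope of method-of-moments estimates across several score samples.

    Each sample set (e.g. decoy predictions at sizes 1000/5000/10000) yields
    one (alpha, beta) point via its raw moments; the elementwise min/max across
    sets is returned as the admissible interval.  Sets with degenerate moments
    are skipped with a warning; if every set is degenerate an error is raised.
    """
    alphas: list[float] = []
    betas: list[float] = []
    for i, s in enumerate(sample_sets):
        arr = _check_open_unit(np.asarray(s, dtype=float), name=f"sample set {i}")
        if arr.size < min_size:
            raise ValueError(
                f"sample set {i} has {arr.size} values; need at least {min_size}"
            )
        try:
            p = mom_estimate(float(arr.mean()), float(arr.var()))
        except DegenerateMomentsError:
            warnings.warn(f"sample set {i} has degenerate moments; skipped")
            continue
        alphas.append(p.alpha)
        betas.append(p.beta)
    if not alphas:
        raise DegenerateMomentsError("all sample sets had degenerate moments")
    return ConstraintRanges(
        alpha_interval=(min(alphas), max(alphas)),
        beta_interval=(min(betas), max(betas)),
        component=component,
    )


def project_into_range(
    params: BetaParams, ranges: ConstraintRanges
) -> tuple[BetaParams, bool]:
    """Clip (alpha, beta) independently into their admissible intervals.

    Returns the (possibly unchanged) parameters and a flag saying whether any
    clipping occurred.  Projection is idempotent.
    """
    a = float(np.clip(params.alpha, *ranges.alpha_interval))
    b = float(np.clip(params.beta, *ranges.beta_interval))
    clipped = (a != params.alpha) or (b != params.beta)
    return (BetaParams(a, b) if clipped else params), clipped


def ranges_around(
    params: BetaParams, fraction: float, component: str = "true_component"
) -> ConstraintRanges:
    """Symmetric relative band [(1-f) v, (1+f) v] around each shape parameter."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    return ConstraintRanges(
        alpha_interval=(params.alpha * (1 - fraction), params.alpha * (1 + fraction)),
        beta_interval=(params.beta * (1 - fraction), params.beta * (1 + fraction)),
        component=component,
    )
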