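"""Modified EM for a two-component beta mixture of scaled binding scores.

The fit alternates a standard E-step (posterior responsibilities under the
current mixture) with a method-of-moments update in place of the usual
likelihood-maximizing M-step: each component's weighted mean and variance are
inverted to beta shape parameters.  Two constraint mechanisms keep the
components attached to their intended roles:

* the *false* component (high IC50, weak binders) can be projected into
  admissible (alpha, beta) ranges derived from decoy score samples, so that it
  is certain to capture the non-binder distribution;
* when the weight of the *true* component collapses to zero while the input
  contains records in the plausible non-binder range (IC50 > 10 000 nM), the
  true component is restricted to a +/-25% band around a method-of-moments
  estimate from the sub-10 000 nM records.  This keeps a pure-decoy input from
  dragging the true component onto the false distribution.

Iteration stops when the maximal relative change across all six parameters
(alpha, beta, pi for both components) falls below the tolerance (1e-5).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .beta_core import (
    BetaParams,
    ConstraintRanges,
    DegenerateMomentsError,
    beta_logpdf,
    mom_estimate,
    project_into_range,
    ranges_around,
    weighted_moments,
)
from .score_io import ScoreTable

__all__ = [
    "MixtureComponent",
    "BetaMixture",
    "FitConfig",
    "FitResult",
    "initialize",
    "e_step",
    "mm_step",
    "relative_change",
    "fit_mixture",
]

logger = logging.getLogger(__name__)

#: below this, a component weight is treated as exactly zero (float-robust)
_PI_ZERO = 1e-12

#: variance is clamped to this fraction of mu*(1-mu) when moments degenerate
_VAR_CLAMP = 0.999

_VAR_FLOOR = 1e-12


@dataclass
class MixtureComponent:
    params: BetaParams
    weight: float

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.weight <= 1.0 + 1e-9):
            raise ValueError(f"weight must be in [0, 1], got {self.weight}")
        self.weight = float(min(max(self.weight, 0.0), 1.0))


@dataclass
class BetaMixture:
    """Two beta components: true = low scaled score (strong predicted binding),
    false = high scaled score.  Weights must sum to 1."""

    true_component: MixtureComponent
    false_component: MixtureComponent

    def __post_init__(self) -> None:
        total = self.true_component.weight + self.false_component.weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")

    @property
    def components(self) -> tuple[MixtureComponent, MixtureComponent]:
        return (self.true_component, self.false_component)

    def is_ordered(self) -> bool:
        """True when the true component's mean does not exceed the false one's."""
        return self.true_component.params.mean <= self.false_component.params.mean

    def log_likelihood(self, xs: np.ndarray) -> float:
        lw = _weighted_logdens(np.asarray(xs, dtype=float), self)
        m = lw.max(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            ll = m[:, 0] + np.log(np.exp(lw - m).sum(axis=1))
        ll = np.where(np.isfinite(m[:, 0]), ll, -np.inf)
        return float(ll.sum())

    def to_dict(self) -> dict:
        return {
            "true": {
                "alpha": self.true_component.params.alpha,
                "beta": self.true_component.params.beta,
                "weight": self.true_component.weight,
            },
            "false": {
                "alpha": self.false_component.params.alpha,
                "beta": self.false_component.params.beta,
                "weight": self.false_component.weight,
            },
        }


@dataclass
class FitConfig:
    """Tunable knobs of the fit; defaults are the method's standard settings.

    tolerance: relative-change termination threshold (1e-5).
    max_iterations: hard cap with a convergence flag, default 1000.
    false_ranges: optional admissible (alpha, beta) intervals for the false
        component, applied by projection at every MM step when provided.
    negative_set_ic50_threshold: IC50 (nM) above which records are treated as
        certain non-binders for the true-component guard (10 000 nM).
    true_deviation_fraction: half-width of the relative band used by the
        guard (0.25 = +/-25% around the initial estimate).
    imbalance_detection: after EM, compare the mixture against a
        single-component beta fit by BIC; when the single model wins, the
        data is declared essentially all-true or all-false and the dominant
        component is fitted to the whole sample (see fit_mixture).
    init_fractions: sorted-split fractions tried as EM starting points; the
        run with the highest final log-likelihood wins.  A single 0.5 entry
        reproduces plain sorted-halving initialization.
    """

    tolerance: float = 1e-5
    max_iterations: int = 1000
    false_ranges: ConstraintRanges | None = None
    negative_set_ic50_threshold: float = 10000.0
    true_deviation_fraction: float = 0.25
    imbalance_detection: bool = True
    init_fractions: tuple[float, ...] = (0.25, 0.5, 0.75)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 < self.true_deviation_fraction < 1.0):
            raise ValueError("true_deviation_fraction must be in (0, 1)")
        if not self.init_fractions or any(
            not (0.0 < f < 1.0) for f in self.init_fractions
        ):
            raise ValueError("init_fractions must be a non-empty tuple in (0, 1)")


@dataclass
class FitResult:
    mixture: BetaMixture
    n_iterations: int
    final_relative_change: float
    converged: bool
    true_constraint_applied: bool = False
    false_clipping_events: int = 0
    single_component: str | None = None  # "all_true" / "all_false" when detected
    loglik_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mixture": self.mixture.to_dict(),
            "n_iterations": self.n_iterations,
            "final_relative_change": self.final_relative_change,
            "converged": self.converged,
            "true_constraint_applied": self.true_constraint_applied,
            "false_clipping_events": self.false_clipping_events,
            "single_component": self.single_component,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def _mom_or_uniform(xs: np.ndarray, label: str) -> BetaParams:
    try:
        return mom_estimate(float(xs.mean()), float(xs.var()))
    except DegenerateMomentsError:
        warnings.warn(
            f"{label} half has degenerate moments at initialization; "
            "falling back to Beta(1, 1)"
        )
        return BetaParams(1.0, 1.0)


def initialize(table: ScoreTable, fraction: float = 0.5) -> BetaMixture:
    """Seed the mixture by a sorted split.

    Records are sorted ascending by scaled score (stable, so ties keep input
    order); the lower ``fraction`` of them — taking the extra record when the
    split does not land on an integer — seeds the true component, the rest
    the false component.  Each part's raw moments are inverted by method of
    moments and the weights start at (fraction, 1 - fraction); the default
    0.5 is plain sorted halving with both weights 0.5.
    """
    if table.n < 4:
        raise ValueError(f"need at least 4 records to initialize, got {table.n}")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    xs = np.sort(table.scaled_scores(), kind="stable")
    split = int(np.ceil(table.n * fraction))
    split = min(max(split, 2), table.n - 2)  # both parts need moments
    lower, upper = xs[:split], xs[split:]
    return BetaMixture(
        true_component=MixtureComponent(_mom_or_uniform(lower, "true"), fraction),
        false_component=MixtureComponent(_mom_or_uniform(upper, "false"), 1 - fraction),
    )


def _weighted_logdens(xs: np.ndarray, mixture: BetaMixture) -> np.ndarray:
    """n x 2 matrix of log(pi_j) + log f(x_i; alpha_j, beta_j)."""
    cols = []
    for comp in mixture.components:
        with np.errstate(divide="ignore"):
            logw = np.log(comp.weight)
        cols.append(logw + beta_logpdf(xs, comp.params))
    return np.column_stack(cols)


def e_step(xs: np.ndarray, mixture: BetaMixture) -> np.ndarray:
    """Posterior responsibilities W[i, j] = pi_j f_j(x_i) / sum_k pi_k f_k(x_i).

    Computed from log densities with rowwise max-subtraction.  Rows where both
    weighted densities underflow to zero get (0.5, 0.5) and are counted in a
    log message.
    """
    xs = np.asarray(xs, dtype=float)
    lw = _weighted_logdens(xs, mixture)
    m = lw.max(axis=1, keepdims=True)
    dead = ~np.isfinite(m[:, 0])
    safe_m = np.where(np.isfinite(m), m, 0.0)
    w = np.exp(lw - safe_m)
    totals = w.sum(axis=1, keepdims=True)
    resp = w / totals
    if dead.any():
        logger.warning("%d points had zero density under both components", dead.sum())
        resp[dead] = 0.5
    return resp


def _component_update(
    xs: np.ndarray, w: np.ndarray, fallback: BetaParams
) -> tuple[BetaParams, bool]:
    """MoM update for one component; returns (params, degenerate_flag)."""
    if w.sum() <= 0.0:
        return fallback, True
    mu, var = weighted_moments(xs, w)
    cap = mu * (1.0 - mu)
    degenerate = False
    if not (0.0 < mu < 1.0):  # cannot happen for xs in (0,1), defensive
        return fallback, True
    if var >= cap * _VAR_CLAMP:
        var = cap * _VAR_CLAMP
        degenerate = True
    if var < _VAR_FLOOR:
        var = _VAR_FLOOR
        degenerate = True
    return mom_estimate(mu, var), degenerate


def mm_step(
    xs: np.ndarray,
    responsibilities: np.ndarray,
    config: FitConfig,
    init_true_ranges: ConstraintRanges | None = None,
    previous: BetaMixture | None = None,
) -> tuple[BetaMixture, int]:
    """Method-of-moments update of weights and shapes from responsibilities.

    pi_j is the mean responsibility; each component's weighted moments are
    inverted to (alpha, beta).  The false component is projected into
    ``config.false_ranges`` when provided, the true component into
    ``init_true_ranges`` when the collapse guard is active.  Degenerate
    moments are clamped to the nearest valid point (variance capped at
    0.999 mu(1-mu)).  Returns the new mixture and the number of clipping
    events on the false component.  ``previous`` supplies fallback parameters
    for a component that received zero total responsibility.
    """
    xs = np.asarray(xs, dtype=float)
    W = np.asarray(responsibilities, dtype=float)
    if W.shape != (xs.size, 2):
        raise ValueError("responsibilities must be n x 2, aligned with xs")
    pi = W.mean(axis=0)
    pi = pi / pi.sum()

    fb_true = previous.true_component.params if previous else BetaParams(1.0, 1.0)
    fb_false = previous.false_component.params if previous else BetaParams(1.0, 1.0)
    true_params, _ = _component_update(xs, W[:, 0], fb_true)
    false_params, _ = _component_update(xs, W[:, 1], fb_false)

    clip_events = 0
    if config.false_ranges is not None:
        false_params, clipped = project_into_range(false_params, config.false_ranges)
        clip_events += int(clipped)
    if init_true_ranges is not None:
        true_params, _ = project_into_range(true_params, init_true_ranges)

    return (
        BetaMixture(
            true_component=MixtureComponent(true_params, float(pi[0])),
            false_component=MixtureComponent(false_params, float(pi[1])),
        ),
        clip_events,
    )


def relative_change(old: BetaMixture, new: BetaMixture) -> float:
    """Maximal relative parameter change between successive iterations.

    k = max over {alpha_1, beta_1, alpha_2, beta_2, pi_1, pi_2} of
    |new - old| / max(|new|, |old|); a parameter that is zero in both steps
    contributes 0.
    """
    pairs = []
    for oc, nc in zip(old.components, new.components):
        pairs.append((oc.params.alpha, nc.params.alpha))
        pairs.append((oc.params.beta, nc.params.beta))
        pairs.append((oc.weight, nc.weight))
    k = 0.0
    for o, n in pairs:
        denom = max(abs(o), abs(n))
        if denom == 0.0:
            continue
        k = max(k, abs(n - o) / denom)
    return k


def _guard_true_ranges(table: ScoreTable, config: FitConfig) -> ConstraintRanges | None:
    """+/-deviation band around the MoM estimate from sub-threshold records."""
    ic50 = table.ic50()
    positives = table.scaled_scores()[ic50 <= config.negative_set_ic50_threshold]
    if positives.size < 2:
        return None
    try:
        base = mom_estimate(float(positives.mean()), float(positives.var()))
    except DegenerateMomentsError:
        return None
    return ranges_around(base, config.true_deviation_fraction, "true_component")


def _run_em(
    xs: np.ndarray,
    table: ScoreTable,
    config: FitConfig,
    mixture: BetaMixture,
    negative_set_nonempty: bool,
) -> tuple[BetaMixture, int, float, bool, ConstraintRanges | None, int, list[float]]:
    """One EM run from a given starting mixture; returns its end state."""
    true_ranges: ConstraintRanges | None = None
    guard_active = False
    false_clip_total = 0
    k = np.inf
    trace: list[float] = []
    it = 0
    for it in range(1, config.max_iterations + 1):
        resp = e_step(xs, mixture)
        new_mixture, clips = mm_step(
            xs,
            resp,
            config,
            init_true_ranges=true_ranges if guard_active else None,
            previous=mixture,
        )
        false_clip_total += clips
        if (
            not guard_active
            and negative_set_nonempty
            and new_mixture.true_component.weight < _PI_ZERO
        ):
            guard_active = True
            true_ranges = _guard_true_ranges(table, config)
            if true_ranges is not None:
                projected, _ = project_into_range(
                    new_mixture.true_component.params, true_ranges
                )
                new_mixture = BetaMixture(
                    true_component=MixtureComponent(
                        projected, new_mixture.true_component.weight
                    ),
                    false_component=new_mixture.false_component,
                )
            else:
                logger.warning(
                    "true-component guard triggered but no usable sub-threshold "
                    "records; leaving component unconstrained"
                )
        k = relative_change(mixture, new_mixture)
        mixture = new_mixture
        trace.append(mixture.log_likelihood(xs))
        if k < config.tolerance:
            break
    return mixture, it, float(k), guard_active, true_ranges, false_clip_total, trace


def fit_mixture(table: ScoreTable, config: FitConfig | None = None) -> FitResult:
    """Run the full modified-EM fit on a scaled score table.

    Alternates :func:`e_step` and :func:`mm_step` until the relative change
    drops below ``config.tolerance`` or ``config.max_iterations`` is reached
    (then ``converged`` is False, not an exception).  EM is started from each
    sorted split in ``config.init_fractions`` and the run with the highest
    final log-likelihood is kept — the halving start alone can settle in a
    degenerate broad-plus-narrow optimum on weakly separated samples.  The
    true-component guard activates — and stays active — the first time
    pi_true falls to zero while the table contains records with IC50 above
    the negative-set threshold.  The fit is fully deterministic.
    """
    config = config or FitConfig()
    if table.n < 4:
        raise ValueError(f"need at least 4 records to fit, got {table.n}")
    xs = table.scaled_scores()
    ic50 = table.ic50()
    negative_set_nonempty = bool(np.any(ic50 > config.negative_set_ic50_threshold))

    best = None
    best_ll = -np.inf
    for fraction in config.init_fractions:
        run = _run_em(
            xs, table, config, initialize(table, fraction), negative_set_nonempty
        )
        ll = run[0].log_likelihood(xs)
        if ll > best_ll:
            best, best_ll = run, ll
    mixture, it, k, guard_active, true_ranges, false_clip_total, trace = best
    converged = k < config.tolerance

    single_label: str | None = None
    if config.imbalance_detection:
        verdict = _detect_imbalance(xs, mixture, negative_set_nonempty, table, config)
        if verdict is not None:
            single_label, single_params = verdict
            if single_label == "all_false":
                # true component must not wander onto the decoy distribution:
                # restrict it to the band around the sub-threshold records
                guard_active = True
                if true_ranges is None:
                    true_ranges = _guard_true_ranges(table, config)
                true_params = mixture.true_component.params
                if true_ranges is not None:
                    true_params, _ = project_into_range(true_params, true_ranges)
                mixture = BetaMixture(
                    true_component=MixtureComponent(true_params, 0.0),
                    false_component=MixtureComponent(single_params, 1.0),
                )
            else:
                mixture = BetaMixture(
                    true_component=MixtureComponent(single_params, 1.0),
                    false_component=MixtureComponent(
                        mixture.false_component.params, 0.0
                    ),
                )
            logger.info("imbalance detected: input is essentially %s", single_label)

    both_live = (
        mixture.true_component.weight > 1e-9
        and mixture.false_component.weight > 1e-9
    )
    if both_live and not mixture.is_ordered():
        raise RuntimeError(
            "fitted true-component mean exceeds false-component mean; "
            "input distribution is pathological for this model"
        )
    return FitResult(
        mixture=mixture,
        n_iterations=it,
        final_relative_change=k,
        converged=converged,
        true_constraint_applied=guard_active and true_ranges is not None,
        false_clipping_events=false_clip_total,
        single_component=single_label,
        loglik_trace=trace,
    )


def _detect_imbalance(
    xs: np.ndarray,
    mixture: BetaMixture,
    negative_set_nonempty: bool,
    table: ScoreTable,
    config: FitConfig,
) -> tuple[str, BetaParams] | None:
    """BIC comparison of the fitted mixture against one beta for all the data.

    A genuinely bimodal input favours the mixture by a wide margin; when a
    single method-of-moments beta explains the sample better (accounting for
    the three extra mixture parameters), the input is declared essentially
    one-sided.  Direction: all-false when records above the negative-set IC50
    threshold exist and the single fit's mean lies above the scaled analog of
    1000 nM (the plausible-binder line); all-true otherwise.
    """
    try:
        single = mom_estimate(float(xs.mean()), float(xs.var()))
    except DegenerateMomentsError:
        return None
    n = xs.size
    ll_single = float(np.sum(beta_logpdf(xs, single)))
    ll_mix = mixture.log_likelihood(xs)
    bic_single = 2.0 * np.log(n) - 2.0 * ll_single
    bic_mix = 5.0 * np.log(n) - 2.0 * ll_mix
    if bic_single >= bic_mix:
        return None
    bound = table.scale_upper_bound or 1.0
    binder_line = min(np.log10(1000.0) / bound, 1.0)
    if negative_set_nonempty and single.mean > binder_line:
        return ("all_false", single)
    return ("all_true", single)
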