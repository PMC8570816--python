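"""Synthetic score mixtures, simulation from fitted parameters, and fit
diagnostics.

The generator emulates the engineered benchmark mixtures used to develop the
method: scores of genuine binders drawn from a low-scaled-score beta
component and decoy scores from a high-scaled-score component, combined at a
configurable ratio (default 1000 true : 4000 false).  Decoy draws whose
back-transformed IC50 would fall below ~1000 nM — decoys that would in fact be
plausible binders — are redrawn, mirroring how such peptides are excluded when
real decoy sets are built.

Fit quality is measured the same two ways as on real data: a quantile-quantile
ordinary-least-squares regression of simulated against observed scores
(R^2 ~ 1, slope ~ 1, intercept ~ 0 for a good fit) and the two-sample
Kolmogorov-Smirnov test (p >= 0.05 means no detectable difference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
from scipy import stats

from .beta_core import BetaParams, beta_cdf
from .em_fit import FitResult
from .score_io import (
    DEFAULT_FIXED_BOUND,
    EPS,
    ScoreRecord,
    ScoreTable,
    ic50_from_scaled,
    scaled_from_ic50,
)

__all__ = [
    "DECOY_EXCLUSION_IC50_NM",
    "SyntheticSpec",
    "FitDiagnostics",
    "generate_synthetic",
    "simulate_from_fit",
    "qq_r_squared",
    "ks_two_sample",
    "evaluate_fit",
]

#: decoys predicted to bind more strongly than this are excluded (redrawn)
DECOY_EXCLUSION_IC50_NM = 1000.0

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class SyntheticSpec:
    """Recipe for one labeled synthetic score table.

    Defaults reproduce the benchmark construction: 1000 true binders from a
    strongly left-shifted beta, 4000 decoys from a right-shifted beta, decoy
    draws below the scaled analog of IC50 1000 nM redrawn.  Set
    ``decoy_exclusion_scaled=None`` to sample the false component untruncated.
    """

    n_true: int = 1000
    n_false: int = 4000
    true_params: BetaParams = field(default_factory=lambda: BetaParams(1.5, 8.0))
    false_params: BetaParams = field(default_factory=lambda: BetaParams(6.0, 2.5))
    decoy_exclusion_scaled: float | None = field(
        default_factory=lambda: float(
            scaled_from_ic50(DECOY_EXCLUSION_IC50_NM, DEFAULT_FIXED_BOUND)
        )
    )
    seed: int = 0
    allele: str = "HLA-SYN"
    scale_upper_bound: float = DEFAULT_FIXED_BOUND

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_false < 0:
            raise ValueError("component sizes must be non-negative")
        if self.n_true + self.n_false < 4:
            raise ValueError("need at least 4 records in total")
        if self.decoy_exclusion_scaled is not None and not (
            0.0 < self.decoy_exclusion_scaled < 1.0
        ):
            raise ValueError("decoy_exclusion_scaled must be in (0, 1)")


def _random_peptides(rng: np.random.Generator, n: int, length: int = 9) -> list[str]:
    # structural realism only; the letters carry no binding semantics
    idx = rng.integers(0, len(_AA), size=(n, length))
    return ["".join(_AA[row]) for row in idx]


def generate_synthetic(spec: SyntheticSpec) -> ScoreTable:
    """Draw a labeled, already-scaled score table from the spec.

    False draws below the decoy-exclusion threshold are redrawn so the decoy
    count is preserved; the spec is rejected as degenerate when fewer than 1%
    of decoy draws would be accepted.  Records carry back-transformed IC50
    values (inverse of the scaling map) and hidden truth labels; rows are
    shuffled so labels are not inferable from position.
    """
    rng = np.random.default_rng(spec.seed)
    true_scores = rng.beta(*spec.true_params.as_tuple(), size=spec.n_true)
    if spec.decoy_exclusion_scaled is not None and spec.n_false > 0:
        accept_p = 1.0 - beta_cdf(spec.decoy_exclusion_scaled, spec.false_params)
        if accept_p < 0.01:
            raise ValueError(
                "degenerate spec: fewer than 1% of decoy draws exceed the "
                f"exclusion threshold {spec.decoy_exclusion_scaled:.3f}"
            )
        false_scores = np.empty(0)
        while false_scores.size < spec.n_false:
            need = spec.n_false - false_scores.size
            draw = rng.beta(*spec.false_params.as_tuple(), size=max(need * 2, 64))
            false_scores = np.concatenate(
                [false_scores, draw[draw >= spec.decoy_exclusion_scaled]]
            )
        false_scores = false_scores[: spec.n_false]
    else:
        false_scores = rng.beta(*spec.false_params.as_tuple(), size=spec.n_false)

    scores = np.clip(
        np.concatenate([true_scores, false_scores]), EPS, 1.0 - EPS
    )
    labels = np.concatenate(
        [np.ones(spec.n_true, dtype=bool), np.zeros(spec.n_false, dtype=bool)]
    )
    perm = rng.permutation(scores.size)
    scores, labels = scores[perm], labels[perm]
    ic50 = ic50_from_scaled(scores, spec.scale_upper_bound)
    peptides = _random_peptides(rng, scores.size)
    records = [
        ScoreRecord(
            peptide=p,
            allele=spec.allele,
            ic50_nm=float(v),
            scaled_score=float(s),
        )
        for p, v, s in zip(peptides, ic50, scores)
    ]
    return ScoreTable(
        records=records,
        dialect="generic",
        allele=spec.allele,
        scale_upper_bound=spec.scale_upper_bound,
        truth_labels=labels,
    )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def simulate_from_fit(fit: FitResult, size: int, seed: int) -> np.ndarray:
    """Sample ``size`` scores from the fitted mixture.

    round(pi_true * size) draws (half away from zero) come from the true
    component and the remainder from the false component, concatenated in that
    order.
    """
    if size < 2:
        raise ValueError("size must be at least 2")
    rng = np.random.default_rng(seed)
    n_true = _round_half_away(fit.mixture.true_component.weight * size)
    n_true = min(max(n_true, 0), size)
    sims = np.concatenate(
        [
            rng.beta(*fit.mixture.true_component.params.as_tuple(), size=n_true),
            rng.beta(*fit.mixture.false_component.params.as_tuple(), size=size - n_true),
        ]
    )
    return np.clip(sims, EPS, 1.0 - EPS)


@dataclass
class FitDiagnostics:
    """Similarity of an observed sample to a simulated one."""

    r_squared: float
    slope: float
    intercept: float
    ks_statistic: float | None = None
    ks_p_value: float | None = None

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "slope": self.slope,
            "intercept": self.intercept,
            "ks_statistic": self.ks_statistic,
            "ks_p_value": self.ks_p_value,
        }


def qq_r_squared(real_sample, simulated_sample) -> FitDiagnostics:
    """Quantile-quantile OLS of simulated against real scores.

    Both samples are sorted; the larger is interpolated onto the quantile grid
    of the smaller; then ordinary least squares of simulated quantiles on real
    quantiles gives R^2, slope and intercept.  Identical samples give exactly
    (1, 1, 0); R^2 alone measures distribution-shape agreement while slope and
    intercept expose scale and location mismatches.
    """
    a = np.sort(np.asarray(real_sample, dtype=float))
    b = np.sort(np.asarray(simulated_sample, dtype=float))
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    if a.std() == 0.0 or b.std() == 0.0:
        raise ValueError("zero variance in a sample; regression undefined")
    m = min(a.size, b.size)
    probs = (np.arange(m) + 0.5) / m
    aq = a if a.size == m else np.quantile(a, probs)
    bq = b if b.size == m else np.quantile(b, probs)
    res = stats.linregress(aq, bq)
    return FitDiagnostics(
        r_squared=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 values")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def evaluate_fit(real_sample, simulated_sample) -> FitDiagnostics:
    """Full diagnostics: Q-Q regression plus KS test in one record."""
    diag = qq_r_squared(real_sample, simulated_sample)
    diag.ks_statistic, diag.ks_p_value = ks_two_sample(real_sample, simulated_sample)
    return diag
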