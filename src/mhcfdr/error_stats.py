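"""Per-peptide global FDR and local FDR (PEP) from a fitted beta mixture.

With F and f the beta CDF and PDF of the two fitted components, a score x
(scaled so that low = strong predicted binding) gets

    FDR(x) = pi_f F_false(x) / (pi_t F_true(x) + pi_f F_false(x))
    PEP(x) = pi_f f_false(x) / (pi_t f_true(x) + pi_f f_false(x))

Global FDR is the expected false fraction among everything accepted at
threshold x; PEP is the posterior probability that this one prediction is
false, and 1 - PEP the probability it is true.

The printed forms of these equations omit the mixture proportions; posterior
probabilities require them, so the weighted form is the default and the
unweighted one is kept behind ``weighted=False`` for strict equation-level
comparison.  The mode used is recorded in run metadata by the CLI.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .beta_core import beta_cdf, beta_logpdf
from .em_fit import BetaMixture, FitResult
from .score_io import EPS, ScoreRecord, ScoreTable

__all__ = [
    "ErrorAnnotation",
    "SelectionResult",
    "compute_fdr",
    "compute_pep",
    "annotate",
    "select_at_fdr",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorAnnotation:
    """Per-record statistics; true_prob is exactly 1 - pep."""

    fdr: float
    pep: float
    true_prob: float

    def __post_init__(self) -> None:
        for name in ("fdr", "pep", "true_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.true_prob != 1.0 - self.pep:
            raise ValueError("true_prob must equal 1 - pep exactly")


def _clamp_open(x: np.ndarray) -> np.ndarray:
    return np.clip(x, EPS, 1.0 - EPS)


def compute_fdr(
    x: np.ndarray | float, mixture: BetaMixture, weighted: bool = True
) -> np.ndarray | float:
    """Global FDR at score threshold x (false fraction among scores <= x).

    Weighted mode multiplies each CDF by its mixture proportion; unweighted
    mode is the bare ratio F_false / (F_true + F_false).  When both terms are
    zero (x below all mass) the FDR is 0.
    """
    arr = _clamp_open(np.asarray(x, dtype=float))
    tc, fc = mixture.true_component, mixture.false_component
    wt = tc.weight if weighted else 1.0
    wf = fc.weight if weighted else 1.0
    num = wf * beta_cdf(arr, fc.params)
    den = wt * beta_cdf(arr, tc.params) + num
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0.0, num / np.maximum(den, 1e-300), 0.0)
    return float(out) if np.isscalar(x) else out


def compute_pep(
    x: np.ndarray | float, mixture: BetaMixture, weighted: bool = True
) -> np.ndarray | float:
    """Local FDR (posterior error probability) at score x.

    Weighted mode is the posterior that the point came from the false
    component; unweighted mode drops the proportions.  Points where both
    densities underflow to zero get 0.5 (no evidence either way); such events
    are logged.
    """
    arr = _clamp_open(np.asarray(x, dtype=float))
    tc, fc = mixture.true_component, mixture.false_component
    with np.errstate(divide="ignore"):
        lt = (np.log(tc.weight) if weighted else 0.0) + beta_logpdf(arr, tc.params)
        lf = (np.log(fc.weight) if weighted else 0.0) + beta_logpdf(arr, fc.params)
    m = np.maximum(lt, lf)
    dead = ~np.isfinite(m)
    safe_m = np.where(dead, 0.0, m)
    et = np.exp(lt - safe_m)
    ef = np.exp(lf - safe_m)
    with np.errstate(invalid="ignore"):
        out = ef / (et + ef)
    n_dead = int(np.count_nonzero(dead))
    if n_dead:
        logger.warning("%d points had zero density under both components", n_dead)
    out = np.where(dead, 0.5, out)
    return float(out) if np.isscalar(x) else out


def annotate(
    table: ScoreTable, fit: FitResult, weighted: bool = True
) -> list[ErrorAnnotation]:
    """One :class:`ErrorAnnotation` per record, preserving record order.

    The table must carry the same scaling used during fitting.
    """
    if not table.is_scaled:
        raise ValueError("table must be scaled before annotation")
    xs = table.scaled_scores()
    fdr = np.asarray(compute_fdr(xs, fit.mixture, weighted=weighted))
    pep = np.asarray(compute_pep(xs, fit.mixture, weighted=weighted))
    return [
        ErrorAnnotation(fdr=float(f), pep=float(p), true_prob=1.0 - float(p))
        for f, p in zip(fdr, pep)
    ]


@dataclass
class SelectionResult:
    records: list[ScoreRecord]
    indices: np.ndarray
    count: int
    score_cut: float | None  # largest scaled score among selected records


def select_at_fdr(
    table: ScoreTable, annotations: list[ErrorAnnotation], threshold: float
) -> SelectionResult:
    """Records whose global FDR is at or below ``threshold`` (in (0, 1])."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    if len(annotations) != table.n:
        raise ValueError("annotations do not align with the table")
    fdr = np.array([a.fdr for a in annotations])
    idx = np.flatnonzero(fdr <= threshold)
    records = [table.records[i] for i in idx]
    cut = max((r.scaled_score for r in records), default=None)
    return SelectionResult(
        records=records, indices=idx, count=len(records), score_cut=cut
    )
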