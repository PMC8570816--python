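"""Reading, validating and scaling MHC class I binding-prediction tables.

Predictors such as NetMHCpan 4.1 and MHCflurry 2.0 report a predicted binding
affinity (IC50, nM; lower = stronger binder) and usually a percentile rank per
peptide.  The mixture model downstream works on log10(IC50) mapped onto the
unit interval, so this module owns the column dialects, record validation and
the scaling map, plus the annotated-output writer.

Scaling: scaled = clamp(log10(ic50), 0, B) / B, then clamped into
[eps, 1 - eps], where B is either the dataset maximum of log10(ic50)
(``dataset_max`` mode, the default) or a fixed bound, by default
log10(50000) ~ 4.7 — the theoretical maximum of the NetMHCpan affinity scale.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EPS",
    "DEFAULT_FIXED_BOUND",
    "FormatError",
    "ScoreRecord",
    "ScoreTable",
    "parse_prediction_table",
    "scale_scores",
    "scaled_from_ic50",
    "ic50_from_scaled",
    "write_annotated_table",
    "write_score_table",
]

#: clamp width keeping scaled scores strictly inside (0, 1); beta densities
#: can be zero or unbounded at the endpoints
EPS = 1e-6

#: log10 of 50 000 nM, the largest affinity NetMHCpan reports (~4.7)
DEFAULT_FIXED_BOUND = math.log10(50000.0)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

# column-name candidates per dialect, in priority order
_DIALECTS: dict[str, dict] = {
    "generic": {
        "sep": None,
        "peptide": ("peptide",),
        "allele": ("allele",),
        "ic50": ("ic50", "ic50_nm", "affinity"),
        "rank": ("percent_rank", "rank"),
    },
    "netmhcpan": {
        "sep": "\t",
        "peptide": ("Peptide",),
        "allele": ("MHC", "HLA"),
        "ic50": ("Aff(nM)", "Aff"),
        "rank": ("%Rank_BA", "%Rank_EL", "%Rank"),
    },
    "mhcflurry": {
        "sep": ",",
        "peptide": ("peptide",),
        "allele": ("allele",),
        "ic50": ("mhcflurry_affinity", "mhcflurry_prediction"),
        "rank": ("mhcflurry_affinity_percentile",),
    },
}


class FormatError(ValueError):
    """Input table does not conform to the declared dialect."""


@dataclass
class ScoreRecord:
    """One peptide's prediction, plus its unit-interval scaled score."""

    peptide: str
    allele: str
    ic50_nm: float
    percent_rank: float | None = None
    scaled_score: float | None = None


@dataclass
class ScoreTable:
    """An ordered, single-allele collection of :class:`ScoreRecord`.

    ``truth_labels`` (True = genuine binder) is populated only by the
    synthetic generator; ``source_frame`` keeps the original parsed columns so
    annotated output can reproduce them verbatim.
    """

    records: list[ScoreRecord]
    dialect: str = "generic"
    allele: str = ""
    scale_upper_bound: float | None = None
    n_clamped_high: int = 0
    truth_labels: np.ndarray | None = None
    source_frame: pd.DataFrame | None = None

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def is_scaled(self) -> bool:
        return self.scale_upper_bound is not None and all(
            r.scaled_score is not None for r in self.records
        )

    def ic50(self) -> np.ndarray:
        return np.array([r.ic50_nm for r in self.records], dtype=float)

    def scaled_scores(self) -> np.ndarray:
        if not self.is_scaled:
            raise ValueError("table has not been scaled; call scale_scores first")
        return np.array([r.scaled_score for r in self.records], dtype=float)


def _resolve_column(df: pd.DataFrame, candidates: Sequence[str]) -> str | None:
    for c in candidates:
        if c in df.columns:
            return c
    return None


def parse_prediction_table(
    source: str | Path | io.TextIOBase, dialect: str = "generic"
) -> ScoreTable:
    """Read a prediction table in one of the supported column dialects.

    ``generic`` expects columns named peptide/allele/ic50(+percent_rank) in a
    TSV or CSV; ``netmhcpan`` and ``mhcflurry`` map the tabular exports of
    those tools.  Rows with non-numeric or non-positive IC50, invalid peptide
    strings or out-of-range percentile ranks are reported by file line number
    as a :class:`FormatError`.  Tables mixing alleles are rejected: the
    mixture models a single allele's score distribution, so multi-allele
    input must be split upstream.
    """
    if dialect not in _DIALECTS:
        raise FormatError(
            f"unknown dialect {dialect!r}; expected one of {sorted(_DIALECTS)}"
        )
    spec = _DIALECTS[dialect]
    read_kwargs = dict(sep=spec["sep"])
    if spec["sep"] is None:
        read_kwargs = dict(sep=None, engine="python")
    try:
        df = pd.read_csv(source, **read_kwargs)
    except pd.errors.EmptyDataError:
        raise FormatError("empty table: no header or data rows") from None
    if df.shape[0] == 0:
        raise FormatError("empty table: header only, no data rows")

    pep_col = _resolve_column(df, spec["peptide"])
    allele_col = _resolve_column(df, spec["allele"])
    ic50_col = _resolve_column(df, spec["ic50"])
    for col, names in (("peptide", pep_col), ("allele", allele_col), ("ic50", ic50_col)):
        if names is None:
            raise FormatError(
                f"dialect {dialect!r}: missing mandatory {col} column "
                f"(looked for {_DIALECTS[dialect][col]})"
            )
    rank_col = _resolve_column(df, spec["rank"])

    ic50 = pd.to_numeric(df[ic50_col], errors="coerce")
    bad_lines: list[int] = []
    reasons: list[str] = []
    for i in range(len(df)):
        line_no = i + 2  # header is file line 1
        v = ic50.iloc[i]
        pep = str(df[pep_col].iloc[i])
        if pd.isna(v) or v <= 0:
            bad_lines.append(line_no)
            reasons.append(f"line {line_no}: IC50 must be a positive number, got {df[ic50_col].iloc[i]!r}")
            continue
        if not (8 <= len(pep) <= 11) or not set(pep) <= AMINO_ACIDS:
            bad_lines.append(line_no)
            reasons.append(
                f"line {line_no}: peptide {pep!r} must be 8-11 standard amino-acid letters"
            )
            continue
        if rank_col is not None and not pd.isna(df[rank_col].iloc[i]):
            r = float(df[rank_col].iloc[i])
            if not (0.0 <= r <= 100.0):
                bad_lines.append(line_no)
                reasons.append(f"line {line_no}: percent rank {r} outside [0, 100]")
    if bad_lines:
        raise FormatError(
            f"{len(bad_lines)} invalid row(s) at line(s) {bad_lines}:\n  "
            + "\n  ".join(reasons)
        )

    alleles = df[allele_col].astype(str).unique()
    if len(alleles) > 1:
        raise FormatError(
            f"table mixes {len(alleles)} alleles ({', '.join(alleles[:5])}...); "
            "the mixture is fitted per allele — split the table upstream"
        )
    if len(df) < 2:
        raise FormatError("need at least 2 records to fit a two-component mixture")

    records = [
        ScoreRecord(
            peptide=str(df[pep_col].iloc[i]),
            allele=str(df[allele_col].iloc[i]),
            ic50_nm=float(ic50.iloc[i]),
            percent_rank=(
                float(df[rank_col].iloc[i])
                if rank_col is not None and not pd.isna(df[rank_col].iloc[i])
                else None
            ),
        )
        for i in range(len(df))
    ]
    return ScoreTable(
        records=records,
        dialect=dialect,
        allele=str(alleles[0]),
        source_frame=df,
    )


def _scale_values(log_ic50: np.ndarray, bound: float) -> tuple[np.ndarray, int]:
    clamped_low = np.clip(log_ic50, 0.0, None)  # sub-1 nM binders map near 0
    n_high = int(np.count_nonzero(clamped_low > bound))
    scaled = np.clip(clamped_low, None, bound) / bound
    return np.clip(scaled, EPS, 1.0 - EPS), n_high


def scaled_from_ic50(
    ic50_nm: np.ndarray | float, bound: float = DEFAULT_FIXED_BOUND
) -> np.ndarray | float:
    """Map IC50 (nM) to the unit interval: clamp(log10(ic50), 0, B) / B."""
    arr = np.asarray(ic50_nm, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("ic50 values must be positive")
    out, _ = _scale_values(np.log10(arr), bound)
    return float(out) if np.isscalar(ic50_nm) else out


def ic50_from_scaled(
    scaled: np.ndarray | float, bound: float = DEFAULT_FIXED_BOUND
) -> np.ndarray | float:
    """Inverse of :func:`scaled_from_ic50` (up to endpoint clamping)."""
    arr = np.asarray(scaled, dtype=float)
    out = np.power(10.0, arr * bound)
    return float(out) if np.isscalar(scaled) else out


def scale_scores(
    table: ScoreTable,
    mode: str = "dataset_max",
    fixed_bound: float = DEFAULT_FIXED_BOUND,
) -> ScoreTable:
    """Scale each record's log10(IC50) onto (0, 1) by dividing by a bound.

    ``dataset_max`` divides by the table's own maximum log10(IC50);
    ``fixed_bound`` divides by ``fixed_bound`` (default log10(50000)) for
    cross-dataset comparability.  Values whose log10 exceeds a fixed bound are
    clamped to 1 - eps and counted in ``n_clamped_high``, not rejected.
    """
    if mode not in ("dataset_max", "fixed_bound"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    ic50 = table.ic50()
    if np.any(ic50 <= 0):
        raise ValueError("all ic50 values must be positive")
    log_ic50 = np.log10(ic50)
    if mode == "dataset_max":
        bound = float(log_ic50.max())
        if bound <= 0:
            raise ValueError(
                "dataset maximum log10(IC50) is not positive; use fixed_bound mode"
            )
    else:
        if fixed_bound <= 0:
            raise ValueError("fixed_bound must be positive")
        bound = float(fixed_bound)
    scaled, n_high = _scale_values(log_ic50, bound)
    records = [replace(r, scaled_score=float(s)) for r, s in zip(table.records, scaled)]
    return replace(
        table,
        records=records,
        scale_upper_bound=bound,
        n_clamped_high=n_high,
    )


def _canonical_frame(table: ScoreTable) -> pd.DataFrame:
    if table.source_frame is not None:
        return table.source_frame.copy()
    data = {
        "peptide": [r.peptide for r in table.records],
        "allele": [r.allele for r in table.records],
        "ic50": [r.ic50_nm for r in table.records],
    }
    if any(r.percent_rank is not None for r in table.records):
        data["percent_rank"] = [r.percent_rank for r in table.records]
    df = pd.DataFrame(data)
    if table.truth_labels is not None:
        df["truth_label"] = np.asarray(table.truth_labels).astype(int)
    return df


def write_score_table(table: ScoreTable, destination: str | Path) -> None:
    """Write a table in the generic TSV dialect (plus truth_label if present)."""
    _canonical_frame(table).to_csv(destination, sep="\t", index=False)


def write_annotated_table(table: ScoreTable, annotations, destination: str | Path) -> None:
    """Write the original columns plus FDR, PEP and TrueProb, row order kept.

    ``annotations`` is the per-record list produced by
    :func:`mhcfdr.error_stats.annotate`; its length must match the table.
    """
    if len(annotations) != table.n:
        raise ValueError(
            f"annotation count {len(annotations)} != record count {table.n}"
        )
    df = _canonical_frame(table)
    df["FDR"] = [a.fdr for a in annotations]
    df["PEP"] = [a.pep for a in annotations]
    df["TrueProb"] = [a.true_prob for a in annotations]
    df.to_csv(destination, sep="\t", index=False)
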