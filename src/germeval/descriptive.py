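"""Per-trait descriptive profiling: mean, SD, CV, range, normality.

The coefficient of variation (CV = 100 x SD/mean, SD with n-1
denominator) is the panel's diversity measure. A Shapiro-Wilk screen
flags departures from normality; it is advisory only and never gates
downstream stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .registry import SFA_CODES, UFA_CODES
from .table import TraitTable

__all__ = [
    "TraitSummary",
    "TableSummary",
    "summarize_trait",
    "summarize_table",
    "check_normality",
    "freedman_diaconis_bins",
]


@dataclass(frozen=True)
class TraitSummary:
    trait_code: str
    n: int
    mean: float
    sd: float
    cv_percent: float | None  #: None marks CV undefined (zero mean)
    min: float
    max: float
    normality_p: float | None = None


@dataclass(frozen=True)
class TableSummary:
    """Summaries for all 34 traits plus panel-level aggregates.

    Aggregates are means of per-accession derived quantities:
    ``protein_plus_oil`` (protein% + oil%), ``sfa_sum`` and ``ufa_sum``
    (sums of the four saturated / unsaturated fatty-acid proportions).
    """

    summaries: tuple[TraitSummary, ...]
    aggregates: dict[str, float]

    def __iter__(self):
        return iter(self.summaries)

    def __getitem__(self, code: str) -> TraitSummary:
        for s in self.summaries:
            if s.trait_code == code:
                return s
        raise KeyError(code)


def summarize_trait(values: np.ndarray, trait_code: str = "") -> TraitSummary:
    """Mean, SD (n-1), CV%, min and max of one trait vector."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValidationError("values must be a 1-D vector")
    if x.size < 2:
        raise ValidationError("need at least 2 observations for a summary")
    if not np.all(np.isfinite(x)):
        raise ValidationError("values must all be finite")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    cv = 100.0 * sd / mean if mean != 0.0 else None
    return TraitSummary(
        trait_code=trait_code,
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv_percent=cv,
        min=float(x.min()),
        max=float(x.max()),
    )


def summarize_table(
    table: TraitTable, normality_alpha: float | None = 0.05
) -> TableSummary:
    """Summaries for every trait in registry order, plus aggregates.

    ``normality_alpha`` enables the Shapiro-Wilk screen (p stored on each
    summary); pass None to skip it (e.g. tiny tables).
    """
    summaries = []
    run_normality = normality_alpha is not None and table.n_accessions >= 8
    for j, entry in enumerate(table.registry):
        s = summarize_trait(table.values[:, j], entry.code)
        if run_normality and s.sd > 0.0:
            _, p, _ = check_normality(table.values[:, j], alpha=normality_alpha)
            s = TraitSummary(**{**s.__dict__, "normality_p": p})
        summaries.append(s)

    sfa = np.sum([table.column(c) for c in SFA_CODES], axis=0)
    ufa = np.sum([table.column(c) for c in UFA_CODES], axis=0)
    aggregates = {
        "protein_plus_oil": float(np.mean(table.column("protein") + table.column("oil"))),
        "sfa_sum": float(np.mean(sfa)),
        "ufa_sum": float(np.mean(ufa)),
    }
    return TableSummary(tuple(summaries), aggregates)


def check_normality(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Shapiro-Wilk normality screen.

    Returns ``(W statistic, p, passed)`` with ``passed = p >= alpha``.
    Requires n >= 8; a constant vector is degenerate and rejected.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8:
        raise ValidationError("normality screen needs n >= 8")
    if np.ptp(x) == 0.0:
        raise DegenerateDataError("constant vector: normality test undefined")
    stat, p = stats.shapiro(x)
    return float(stat), float(p), bool(p >= alpha)


def freedman_diaconis_bins(values: np.ndarray) -> int:
    """Freedman-Diaconis histogram bin count (>= 1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        return 1
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0.0:
        return 1
    width = 2.0 * iqr / x.size ** (1.0 / 3.0)
    return max(1, math.ceil(float(np.ptp(x)) / width))
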