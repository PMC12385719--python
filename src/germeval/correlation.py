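"""Pairwise Pearson correlation over the 34 traits, with significance.

Two-sided p-values come from the exact t transform
``t = r * sqrt((n - 2) / (1 - r^2))`` with n-2 degrees of freedom.
Stars follow the usual display convention: ``**`` for p < 0.01, ``*``
for 0.01 <= p < 0.05, empty otherwise. The 561 pairs are shown
uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .registry import FAMILIES
from .table import TraitTable

__all__ = ["CorrelationResult", "pearson_matrix", "cross_block_report"]


@dataclass(frozen=True)
class CorrelationResult:
    trait_codes: tuple[str, ...]
    r_matrix: np.ndarray
    p_matrix: np.ndarray
    n: int

    @property
    def star_matrix(self) -> np.ndarray:
        stars = np.where(
            self.p_matrix < 0.01, "**", np.where(self.p_matrix < 0.05, "*", "")
        ).astype(object)
        np.fill_diagonal(stars, "")
        return stars

    def pair(self, a: str, b: str) -> tuple[float, float, str]:
        """(r, p, stars) for a trait pair, by code."""
        i = self.trait_codes.index(a)
        j = self.trait_codes.index(b)
        return (
            float(self.r_matrix[i, j]),
            float(self.p_matrix[i, j]),
            str(self.star_matrix[i, j]),
        )


def pearson_matrix(table: TraitTable) -> CorrelationResult:
    """Full Pearson correlation matrix with two-sided p-values."""
    X = table.values
    n = X.shape[0]
    if n < 3:
        raise ValidationError("correlation needs at least 3 accessions")
    spans = np.ptp(X, axis=0)
    constant = [c for c, s in zip(table.registry.codes, spans) if s == 0.0]
    if constant:
        raise DegenerateDataError(
            f"constant trait column(s): {', '.join(constant)}"
        )
    r = np.corrcoef(X, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(p), 0.0, p)  # |r| == 1 -> t infinite -> p = 0
    np.fill_diagonal(p, 0.0)
    return CorrelationResult(
        trait_codes=tuple(table.registry.codes), r_matrix=r, p_matrix=p, n=n
    )


def cross_block_report(
    result: CorrelationResult,
    table: TraitTable,
    block_a: str,
    block_b: str,
) -> list[tuple[tuple[str, str], float, str]]:
    """All pairs between two trait families, strongest |r| first.

    For a family against itself only distinct unordered pairs are
    listed. Ties in |r| break by registry order of the pair.
    """
    for fam in (block_a, block_b):
        if fam not in FAMILIES:
            raise ValidationError(f"unknown trait family {fam!r}")
    reg = table.registry
    ia = reg.family_indices(block_a)
    ib = reg.family_indices(block_b)
    if block_a == block_b:
        pairs = [(i, j) for k, i in enumerate(ia) for j in ia[k + 1:]]
    else:
        pairs = [(min(i, j), max(i, j)) for i in ia for j in ib]
    stars = result.star_matrix
    rows = [
        (
            (reg.codes[i], reg.codes[j]),
            float(result.r_matrix[i, j]),
            str(stars[i, j]),
        )
        for i, j in pairs
    ]
    order = sorted(
        range(len(rows)), key=lambda k: (-abs(rows[k][1]), pairs[k][0], pairs[k][1])
    )
    return [rows[k] for k in order]
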