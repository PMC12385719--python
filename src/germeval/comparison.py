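"""Group comparison: one-way ANOVA, Tukey HSD, compact letter display.

Each trait is compared across origin groups or breeding periods with a
one-way ANOVA; pairwise differences are resolved with Tukey's HSD
(Tukey-Kramer for the unbalanced origin groups) and summarized as the
agronomy-standard compact letter display: groups sharing a letter are
not significantly different at the chosen alpha. Per the study design,
no multiple-testing correction is applied across traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError
from .table import ORIGIN_LEVELS, PERIOD_LEVELS, TraitTable

__all__ = [
    "AnovaResult",
    "one_way_anova",
    "tukey_hsd",
    "compact_letter_display",
    "anova_with_letters",
    "count_significant_traits",
]

GROUPINGS = {"origin": ORIGIN_LEVELS, "period": PERIOD_LEVELS}


@dataclass(frozen=True)
class AnovaResult:
    trait_code: str
    grouping_variable: str
    f_statistic: float
    p_value: float
    levels: tuple[str, ...]
    group_means: tuple[float, ...]
    letters: tuple[str, ...]


def _split_groups(
    values: np.ndarray, groups: np.ndarray, levels: tuple[str, ...] | None
) -> tuple[tuple[str, ...], list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have equal length")
    if levels is None:
        seen: list[str] = []
        for g in groups:
            if g not in seen:
                seen.append(str(g))
        levels = tuple(seen)
    else:
        levels = tuple(lv for lv in levels if np.any(groups == lv))
    if len(levels) < 2:
        raise ValidationError("need at least 2 groups")
    samples = [values[groups == lv] for lv in levels]
    for lv, s in zip(levels, samples):
        if s.size < 2:
            raise ValidationError(f"group {lv!r} has fewer than 2 observations")
    return levels, samples


def one_way_anova(
    values: np.ndarray,
    groups: np.ndarray,
    levels: tuple[str, ...] | None = None,
) -> tuple[float, float]:
    """Classic one-way ANOVA F and p.

    F is the between/within mean-square ratio with (k-1, N-k) degrees of
    freedom. Degenerate case: zero within-group variance with equal
    group means is defined as F = 0, p = 1.
    """
    _, samples = _split_groups(values, groups, levels)
    within_ss = sum(float(np.sum((s - s.mean()) ** 2)) for s in samples)
    means = [s.mean() for s in samples]
    if within_ss == 0.0 and np.ptp(means) == 0.0:
        return 0.0, 1.0
    f, p = stats.f_oneway(*samples)
    return float(f), float(p)


def tukey_hsd(
    values: np.ndarray,
    groups: np.ndarray,
    levels: tuple[str, ...] | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Tukey HSD pairwise adjusted p-values.

    Uses the studentized-range distribution with the Tukey-Kramer
    unequal-n standard errors. Returns the level order and the symmetric
    p matrix with 1.0 on the diagonal (a level never differs from
    itself).
    """
    levels, samples = _split_groups(values, groups, levels)
    res = stats.tukey_hsd(*samples)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.clip((p + p.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(p, 1.0)
    return levels, p


def compact_letter_display(
    significant: np.ndarray,
    level_order: tuple[str, ...],
    means: np.ndarray | None = None,
) -> tuple[str, ...]:
    """Compact letter display via the insert-and-absorb algorithm.

    ``significant[i, j]`` is True when levels i and j differ
    significantly. Two levels share a letter iff they are NOT
    significantly different. Letters are assigned so that levels with
    larger means (when given) receive earlier letters; the result is
    deterministic.
    """
    sig = np.asarray(significant, dtype=bool)
    k = len(level_order)
    if sig.shape != (k, k):
        raise ValidationError("significance matrix shape must match level count")
    if not np.array_equal(sig, sig.T):
        raise ValidationError("significance matrix must be symmetric")
    if np.any(np.diag(sig)):
        raise ValidationError("a level cannot differ from itself")

    # rank levels by descending mean (stable; identity order if no means)
    if means is None:
        rank = list(range(k))
    else:
        rank = sorted(range(k), key=lambda i: (-float(means[i]), i))
    pos = {lvl: r for r, lvl in enumerate(rank)}  # level index -> rank

    columns: list[set[int]] = [set(range(k))]
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k) if sig[i, j]]
    for i, j in pairs:
        new_columns: list[set[int]] = []
        for col in columns:
            if i in col and j in col:
                new_columns.append(col - {i})
                new_columns.append(col - {j})
            else:
                new_columns.append(col)
        # absorb: drop empty columns, proper subsets, and duplicates
        columns = []
        for c in new_columns:
            if not c or any(c < d for d in new_columns) or c in columns:
                continue
            columns.append(c)

    # order columns by the rank of their best (largest-mean) member,
    # then by their sorted rank tuple for determinism
    columns.sort(key=lambda c: tuple(sorted(pos[i] for i in c)))
    letters = ["" for _ in range(k)]
    for letter_i, col in enumerate(columns):
        ch = chr(ord("a") + letter_i) if letter_i < 26 else f"z{letter_i - 25}"
        for i in col:
            letters[i] += ch
    return tuple("".join(sorted(s)) for s in letters)


def anova_with_letters(
    values: np.ndarray,
    groups: np.ndarray,
    trait_code: str = "",
    grouping_variable: str = "",
    alpha: float = 0.05,
    levels: tuple[str, ...] | None = None,
) -> AnovaResult:
    """ANOVA + Tukey + compact letter display for one trait."""
    f, p = one_way_anova(values, groups, levels)
    lvls, pmat = tukey_hsd(values, groups, levels)
    means = np.array([np.asarray(values, float)[np.asarray(groups, object) == lv].mean() for lv in lvls])
    letters = compact_letter_display(pmat < alpha, lvls, means)
    return AnovaResult(
        trait_code=trait_code,
        grouping_variable=grouping_variable,
        f_statistic=f,
        p_value=p,
        levels=lvls,
        group_means=tuple(float(m) for m in means),
        letters=letters,
    )


def count_significant_traits(
    table: TraitTable,
    grouping: str = "origin",
    alpha: float = 0.05,
) -> tuple[int, dict[str, bool]]:
    """Count nutritional traits with a significant one-way ANOVA.

    Runs the ANOVA for each of the 26 nutritional traits (protein, oil,
    amino acids, fatty acids) across the chosen grouping; p-values are
    uncorrected, matching the study design. Returns the count and
    per-trait flags.
    """
    if grouping not in GROUPINGS:
        raise ValidationError(f"grouping must be one of {sorted(GROUPINGS)}")
    groups = table.origin if grouping == "origin" else table.period
    flags: dict[str, bool] = {}
    for code in table.registry.nutritional_codes:
        _, p = one_way_anova(table.column(code), groups, GROUPINGS[grouping])
        flags[code] = bool(p < alpha)
    return sum(flags.values()), flags
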