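"""PCA + fuzzy-membership-function composite scoring of accessions.

The comprehensive evaluation chain:

1. standardize the 34 traits to zero mean / unit SD (n-1 denominator);
2. eigendecompose the sample correlation matrix (correlation-matrix
   PCA, so the eigenvalues sum to the trait count p);
3. retain components with eigenvalue strictly greater than 1 (Kaiser
   criterion); each component's contribution rate is CR_i = lambda_i/p;
4. weight retained components W_i = CR_i / sum(CR_retained)
   = lambda_i / sum(lambda_retained);
5. min-max normalize each retained component's scores to a fuzzy
   membership U_i(x) = (X_i - X_min) / (X_max - X_min) in [0, 1];
6. combine into the comprehensive score F = sum_i U_i * W_i in [0, 1];
7. rank accessions by F (descending, ties by accession id) and flag the
   top fraction (default 5%, elite count = ceil(fraction * n)).

Because F is not invariant to the arbitrary sign of an eigenvector,
loadings are oriented deterministically: each column is flipped, if
needed, so the sum of its loadings on higher-desirability traits minus
those on lower-desirability traits is non-negative; when that signed
sum is (numerically) zero — e.g. when no desirability is declared — the
entry with the largest magnitude is made positive. Under this fixed
convention F is invariant to positive affine rescaling of any trait.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError, ValidationError
from .table import TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "PcaModel",
    "FmfResult",
    "standardize",
    "fit_pca",
    "select_components",
    "compute_weights",
    "membership_normalize",
    "composite_score",
    "rank_and_select",
    "evaluate",
]

_SIGN_TOL = 1e-9


@dataclass
class PcaModel:
    """Correlation-matrix PCA fit.

    ``loadings`` has unit-norm columns (trait x component);
    ``scores = z @ loadings`` (accession x component);
    ``contribution_rates`` are lambda_i / p over all p components.
    """

    trait_means: np.ndarray
    trait_sds: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    contribution_rates: np.ndarray
    retained_mask: np.ndarray

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


@dataclass
class FmfResult:
    """Composite scoring output: memberships, weights, F, rank, elite."""

    accession_ids: list[str]
    retained: list[int]
    weights: np.ndarray
    memberships: np.ndarray
    f_values: np.ndarray
    ranks: np.ndarray
    elite: np.ndarray

    @property
    def elite_ids(self) -> list[str]:
        return [a for a, e in zip(self.accession_ids, self.elite) if e]


def standardize(
    values: np.ndarray, trait_codes: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize to mean 0, SD 1 (n-1 denominator)."""
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValidationError("standardize needs a 2-D matrix with n >= 3")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    degenerate = np.ptp(X, axis=0) == 0.0
    if np.any(degenerate):
        j = int(np.argmax(degenerate))
        name = trait_codes[j] if trait_codes else f"column {j}"
        raise DegenerateDataError(f"constant trait {name}: cannot standardize")
    return (X - means) / sds, means, sds


def _orient_loadings(loadings: np.ndarray, desirability: np.ndarray | None) -> np.ndarray:
    """Apply the deterministic sign convention column by column."""
    L = loadings.copy()
    for j in range(L.shape[1]):
        col = L[:, j]
        s = float(np.dot(desirability, col)) if desirability is not None else 0.0
        if s < -_SIGN_TOL:
            L[:, j] = -col
        elif abs(s) <= _SIGN_TOL:
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                L[:, j] = -col
    return L


def fit_pca(
    z: np.ndarray,
    desirability: np.ndarray | list[int] | None = None,
    means: np.ndarray | None = None,
    sds: np.ndarray | None = None,
) -> PcaModel:
    """Eigendecompose the sample correlation matrix of standardized data.

    ``desirability`` is an optional per-trait vector of +1 / -1 / 0 used
    by the sign convention. Handles p <= n and p > n alike (the p x p
    correlation matrix is decomposed either way).
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    corr = z.T @ z / (n - 1)
    corr = (corr + corr.T) / 2.0
    try:
        w, V = np.linalg.eigh(corr)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - eigh on sym never fails
        raise DegenerateDataError(f"eigendecomposition failed: {exc}") from exc
    order = np.argsort(w)[::-1]
    w = np.clip(w[order], 0.0, None)
    V = V[:, order]
    if desirability is not None:
        desirability = np.asarray(desirability, dtype=float)
    V = _orient_loadings(V, desirability)
    scores = z @ V
    return PcaModel(
        trait_means=means if means is not None else np.zeros(p),
        trait_sds=sds if sds is not None else np.ones(p),
        eigenvalues=w,
        loadings=V,
        scores=scores,
        contribution_rates=w / p,
        retained_mask=w > 1.0,
    )


def select_components(model: PcaModel, threshold: float = 1.0) -> list[int]:
    """Kaiser criterion: indices of components with eigenvalue > threshold."""
    retained = [i for i, lam in enumerate(model.eigenvalues) if lam > threshold]
    if not retained:
        raise DegenerateDataError(
            f"no eigenvalue exceeds {threshold}; lower the threshold "
            f"(largest eigenvalue is {model.eigenvalues.max():.4f})"
        )
    return retained


def compute_weights(model: PcaModel, retained: list[int]) -> np.ndarray:
    """W_i = CR_i / sum over retained CR_j = lambda_i / sum lambda_retained."""
    if not retained:
        raise ValidationError("retained component list is empty")
    lam = model.eigenvalues[retained]
    return lam / lam.sum()


def membership_normalize(
    scores: np.ndarray, degenerate_value: float | None = None
) -> np.ndarray:
    """Min-max memberships U = (X - Xmin) / (Xmax - Xmin), per column.

    Each column attains exactly 0 and exactly 1 (modulo ties). A column
    with zero range raises unless ``degenerate_value`` supplies the
    constant membership to assign instead (conventionally 0.5).
    """
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] < 2:
        raise ValidationError("membership normalization needs n >= 2")
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    span = hi - lo
    U = np.empty_like(X)
    for j in range(X.shape[1]):
        if span[j] == 0.0:
            if degenerate_value is None:
                raise DegenerateDataError(
                    f"component {j} has zero score range; pass degenerate_value "
                    "(e.g. 0.5) to map it to a constant membership"
                )
            U[:, j] = degenerate_value
        else:
            U[:, j] = (X[:, j] - lo[j]) / span[j]
    return U


def composite_score(U: np.ndarray, W: np.ndarray) -> np.ndarray:
    """F = U . W per accession; in [0, 1] when U is and W sums to 1."""
    U = np.asarray(U, dtype=float)
    W = np.asarray(W, dtype=float)
    if U.ndim != 2 or U.shape[1] != W.size:
        raise ValidationError(
            f"membership columns ({U.shape[1] if U.ndim == 2 else '?'}) "
            f"must match weight count ({W.size})"
        )
    return U @ W


def rank_and_select(
    f_values: np.ndarray,
    accession_ids: list[str],
    proportion: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Rank by descending F (ties by ascending id) and flag the elite.

    The elite count is ``ceil(proportion * n)``; for a 259-accession
    panel at 5% that is 13.
    """
    F = np.asarray(f_values, dtype=float)
    n = F.size
    if n < 1:
        raise ValidationError("need at least one accession")
    if not (0.0 < proportion <= 1.0):
        raise ValidationError("proportion must be in (0, 1]")
    order = sorted(range(n), key=lambda i: (-F[i], accession_ids[i]))
    ranks = np.empty(n, dtype=int)
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    k = math.ceil(proportion * n)
    elite = ranks <= k
    return ranks, elite


def evaluate(
    table: TraitTable,
    threshold: float = 1.0,
    proportion: float = 0.05,
) -> tuple[PcaModel, FmfResult]:
    """Run the full composite evaluation on a trait table."""
    z, means, sds = standardize(table.values, table.registry.codes)
    model = fit_pca(
        z,
        desirability=np.array(table.registry.desirability_signs(), dtype=float),
        means=means,
        sds=sds,
    )
    retained = select_components(model, threshold)
    W = compute_weights(model, retained)
    U = membership_normalize(model.scores[:, retained])
    F = composite_score(U, W)
    ranks, elite = rank_and_select(F, table.accession_ids, proportion)
    logger.info(
        "retained %d/%d components (eigenvalues %s); weights %s; %d elite",
        len(retained),
        model.n_components,
        np.round(model.eigenvalues[retained], 3).tolist(),
        np.round(W, 4).tolist(),
        int(elite.sum()),
    )
    return model, FmfResult(
        accession_ids=list(table.accession_ids),
        retained=retained,
        weights=W,
        memberships=U,
        f_values=F,
        ranks=ranks,
        elite=elite,
    )
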