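"""Hierarchical clustering of accessions on standardized traits.

Agglomerative clustering (Ward linkage on Euclidean distance by
default) over the standardized 34-trait matrix, cut into k groups
(default 4). Cluster labels are canonicalized — 1..k by descending
cluster size, ties by the smallest member accession id — so identities
are stable across runs and row orders. Per-cluster trait profiling
reuses the group-comparison machinery.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy

from .comparison import AnovaResult, anova_with_letters
from .errors import DegenerateDataError, ValidationError
from .pca_fmf import standardize
from .table import TraitTable

__all__ = ["ClusterAssignment", "hierarchical_cluster", "profile_clusters"]

LINKAGES = ("ward", "average", "complete")


@dataclass
class ClusterAssignment:
    accession_ids: list[str]
    labels: np.ndarray  # 1..k, canonical
    k: int
    linkage_method: str
    linkage_matrix: np.ndarray
    cophenetic_distances: np.ndarray

    def members(self, label: int) -> list[str]:
        return [a for a, l in zip(self.accession_ids, self.labels) if l == label]

    @property
    def sizes(self) -> list[int]:
        return [int(np.sum(self.labels == l)) for l in range(1, self.k + 1)]

    def to_newick(self) -> str:
        """Dendrogram as a newick string with accession ids as tips."""
        from skbio import TreeNode  # deferred: skbio import is heavy

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, self.accession_ids)
        buf = io.StringIO()
        tree.write(buf)
        return buf.getvalue()

    def silhouette(self, z: np.ndarray) -> float:
        """Mean silhouette width of the assignment on the given matrix."""
        from sklearn.metrics import silhouette_score

        if self.k < 2 or self.k >= len(self.accession_ids):
            raise ValidationError("silhouette needs 2 <= k < n")
        return float(silhouette_score(z, self.labels))


def _canonical_labels(raw: np.ndarray, ids: list[str], k: int) -> np.ndarray:
    """Relabel clusters 1..k by descending size, ties by smallest member id."""
    clusters = sorted(
        set(int(l) for l in raw),
        key=lambda l: (-int(np.sum(raw == l)), min(ids[i] for i in np.flatnonzero(raw == l))),
    )
    mapping = {old: new for new, old in enumerate(clusters, start=1)}
    return np.array([mapping[int(l)] for l in raw], dtype=int)


def hierarchical_cluster(
    table: TraitTable,
    k: int = 4,
    linkage: str = "ward",
) -> ClusterAssignment:
    """Cluster accessions on standardized traits and cut into k groups."""
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}")
    n = table.n_accessions
    if not (1 <= k <= n):
        raise ValidationError(f"need 1 <= k <= n ({k=}, {n=})")
    z, _, _ = standardize(table.values, table.registry.codes)
    Z = hierarchy.linkage(z, method=linkage, metric="euclidean")
    raw = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = _canonical_labels(raw, table.accession_ids, k)
    coph = hierarchy.cophenet(Z)
    return ClusterAssignment(
        accession_ids=list(table.accession_ids),
        labels=labels,
        k=int(labels.max()),
        linkage_method=linkage,
        linkage_matrix=Z,
        cophenetic_distances=np.asarray(coph),
    )


def profile_clusters(
    table: TraitTable,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
) -> tuple[int, list[AnovaResult]]:
    """Per-trait ANOVA (+ Tukey letters) across clusters.

    Returns the number of traits differing significantly at ``alpha``
    and the per-trait results. A singleton cluster cannot enter an
    ANOVA and is surfaced as an error naming it.
    """
    if assignment.accession_ids != list(table.accession_ids):
        raise ValidationError("assignment does not match the table's accessions")
    for label in range(1, assignment.k + 1):
        if int(np.sum(assignment.labels == label)) < 2:
            raise DegenerateDataError(
                f"cluster {label} is a singleton; per-cluster ANOVA undefined"
            )
    groups = np.array([str(l) for l in assignment.labels], dtype=object)
    levels = tuple(str(l) for l in range(1, assignment.k + 1))
    results = []
    n_sig = 0
    for code in table.registry.codes:
        res = anova_with_letters(
            table.column(code), groups,
            trait_code=code, grouping_variable="cluster",
            alpha=alpha, levels=levels,
        )
        results.append(res)
        if res.p_value < alpha:
            n_sig += 1
    return n_sig, results
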