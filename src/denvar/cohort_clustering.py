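"""Subject stratification: JSD hierarchical clustering and the two comparators.

Three ways of grouping subjects are implemented side by side:

* hierarchical clustering of the pairwise Jensen-Shannon distance matrix
  (the threshold-free route);
* the classical two-threshold rule — a cell is "positive" when its scaled
  intensity exceeds t1, and a subject is assigned to the high group when its
  positive-cell proportion exceeds t2;
* K-means on per-subject vectors of extreme marker quantiles.

Agreement between partitions is quantified with the Rand index and the
Hubert-Arabie adjusted Rand index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score, rand_score

from ._errors import EmptyInputError, ParameterError
from .core_data import SubjectSamples
from .density_distance import DistanceMatrix

LINKAGE_RULES = ("complete", "average", "ward")


@dataclass
class ClusterLabels:
    """Integer group assignment per subject, with method provenance."""

    subject_ids: list[str]
    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.subject_ids),):
            raise ParameterError("labels and subject ids differ in length")
        uniq = np.unique(self.labels)
        if uniq.min() < 0:
            raise ParameterError("labels must be non-negative integers")

    @property
    def n_groups(self) -> int:
        return int(np.unique(self.labels).size)


@dataclass
class ThresholdParams:
    """Positivity cutoff t1 (value in [0,1] or a "qXX" pooled-quantile spec)
    and proportion cutoff t2 in [0,1]."""

    t1: float | str
    t2: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t2 <= 1.0:
            raise ParameterError("t2 must lie in [0, 1]")
        if isinstance(self.t1, str):
            if not self.t1.startswith("q"):
                raise ParameterError("quantile spec must look like 'q95'")
            level = float(self.t1[1:]) / 100.0
            if not 0.0 < level < 1.0:
                raise ParameterError("quantile level must be in (0, 100)")
        elif not 0.0 <= float(self.t1) <= 1.0:
            raise ParameterError("t1 must lie in [0, 1]")

    def resolve_t1(self, pooled: np.ndarray) -> float:
        """Absolute cutoff, computed from pooled cohort data for 'qXX' specs."""
        if isinstance(self.t1, str):
            if pooled.size == 0:
                raise EmptyInputError("cannot resolve quantile cutoff on empty cohort")
            return float(np.quantile(pooled, float(self.t1[1:]) / 100.0))
        return float(self.t1)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel groups as 0..K-1 in order of first appearance (deterministic)."""
    out = np.empty(raw.shape, dtype=int)
    mapping: dict[int, int] = {}
    for i, v in enumerate(raw):
        if v not in mapping:
            mapping[v] = len(mapping)
        out[i] = mapping[v]
    return out


def _classical_mds(D: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """Classical (Torgerson) MDS embedding of a distance matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    keep = w > 1e-10
    if n_components is not None:
        keep[n_components:] = False
    return V[:, keep] * np.sqrt(w[keep])


def hierarchical_cluster(
    D: DistanceMatrix, k: int = 2, linkage_rule: str = "complete"
) -> ClusterLabels:
    """Agglomerative clustering of the precomputed distance matrix, cut at k.

    ``complete`` (default) and ``average`` operate directly on the distances;
    ``ward`` first embeds the subjects with classical MDS (Ward requires
    Euclidean geometry).  Output is deterministic for a fixed input; scipy's
    first-index tie-breaking applies when merge heights tie.
    """
    n = D.n_subjects
    if not 2 <= k <= n:
        raise ParameterError(f"k must be in [2, {n}]")
    if linkage_rule not in LINKAGE_RULES:
        raise ParameterError(f"linkage must be one of {LINKAGE_RULES}")
    if linkage_rule == "ward":
        X = _classical_mds(D.values)
        Z = linkage(X, method="ward")
    else:
        Z = linkage(squareform(D.values, checks=False), method=linkage_rule)
    raw = fcluster(Z, t=k, criterion="maxclust")
    return ClusterLabels(
        subject_ids=list(D.subject_ids),
        labels=_canonical_labels(raw),
        method="jsd-hierarchical",
        params={"k": k, "linkage": linkage_rule},
    )


def threshold_cluster(
    samples: dict[str, SubjectSamples] | dict[str, np.ndarray],
    params: ThresholdParams,
) -> ClusterLabels:
    """Two-threshold positivity clustering.

    p_j = #{x > t1} / n_j per subject; label 1 when p_j > t2.  The per-subject
    positive proportions are returned in ``params["proportions"]``.
    """
    if not samples:
        raise EmptyInputError("no subjects")
    ids = [str(k) for k in samples]
    arrays = [
        v.values if isinstance(v, SubjectSamples) else np.asarray(v, dtype=float)
        for v in samples.values()
    ]
    pooled = np.concatenate(arrays)
    t1 = params.resolve_t1(pooled)
    props = np.array([(a > t1).mean() for a in arrays])
    labels = (props > params.t2).astype(int)
    return ClusterLabels(
        subject_ids=ids,
        labels=labels,
        method="threshold",
        params={
            "t1_spec": params.t1,
            "t1_resolved": t1,
            "t2": params.t2,
            "proportions": props,
        },
    )


def quantile_cluster(
    samples: dict[str, SubjectSamples] | dict[str, np.ndarray],
    quantile_levels: tuple[float, ...] = (0.975, 0.99, 0.995),
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterLabels:
    """K-means on per-subject vectors of marker quantiles.

    Quantiles use the conventional linear-interpolation definition.  K-means
    runs ``n_init`` seeded restarts; the best-inertia solution is kept.
    """
    if not quantile_levels or not all(0.0 < q < 1.0 for q in quantile_levels):
        raise ParameterError("quantile levels must lie in (0, 1)")
    ids = [str(kk) for kk in samples]
    arrays = [
        v.values if isinstance(v, SubjectSamples) else np.asarray(v, dtype=float)
        for v in samples.values()
    ]
    for sid, a in zip(ids, arrays):
        if a.size < 2:
            warnings.warn(
                f"subject {sid}: quantiles of a single value are degenerate",
                stacklevel=2,
            )
    Q = np.vstack([np.quantile(a, quantile_levels) for a in arrays])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(Q)
    return ClusterLabels(
        subject_ids=ids,
        labels=_canonical_labels(km.labels_),
        method="quantile-kmeans",
        params={
            "quantile_levels": tuple(quantile_levels),
            "k": k,
            "seed": seed,
            "inertia": float(km.inertia_),
        },
    )


def rand_indices(a: ClusterLabels, b: ClusterLabels) -> tuple[float, float]:
    """(Rand index, Hubert-Arabie adjusted Rand index) between two partitions."""
    if a.subject_ids != b.subject_ids:
        raise ParameterError("partitions cover different subjects (or ordering)")
    return (
        float(rand_score(a.labels, b.labels)),
        float(adjusted_rand_score(a.labels, b.labels)),
    )
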