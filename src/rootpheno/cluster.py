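"""Partitioning-around-medoids clustering of drought root phenotypes.

PAM is implemented from scratch — deterministic BUILD + SWAP on a
precomputed dissimilarity matrix — together with silhouette widths, average-
silhouette k selection and a PCA projection for inspecting cluster
separation.  Inputs are genotype means standardized within one experiment
under drought, following standard practice for mixed-unit trait sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ClusterModel",
    "standardize",
    "pam_fit",
    "silhouette",
    "choose_k",
    "pca_scores",
    "canonicalize_labels",
]


@dataclass
class FeatureMatrix:
    """Standardized unit × trait matrix with its provenance.

    ``X`` holds z-scores (unit ids in the index); ``centers``/``scales`` are
    the per-trait constants used, so raw values can be reconstructed.
    Units dropped for missing traits and constant traits dropped outright
    are recorded rather than silently discarded.
    """

    X: pd.DataFrame
    centers: pd.Series
    scales: pd.Series
    excluded_units: list[str] = field(default_factory=list)
    dropped_traits: list[str] = field(default_factory=list)
    experiment: str | None = None
    treatment: str | None = None

    @property
    def values(self) -> np.ndarray:
        return self.X.to_numpy(dtype=float)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.X.index)


@dataclass
class ClusterModel:
    """A fitted PAM partition plus its diagnostics."""

    k: int
    medoid_indices: list[int]          # row positions into the feature matrix
    medoid_ids: list[str]
    labels: np.ndarray                 # cluster index per unit, 0..k-1
    unit_ids: list[str]
    total_cost: float
    silhouette_values: np.ndarray | None = None
    avg_silhouette: float | None = None
    avg_sil_by_k: dict[int, float] = field(default_factory=dict)
    wss_by_k: dict[int, float] = field(default_factory=dict)

    def assignments(self) -> pd.DataFrame:
        out = pd.DataFrame({"unit": self.unit_ids, "cluster": self.labels})
        if self.silhouette_values is not None:
            out["silhouette"] = self.silhouette_values
        return out

    def to_csv_pair(self, path: str | Path) -> None:
        """Write assignments to ``path`` and medoids next to it (``*_medoids.csv``)."""
        path = Path(path)
        self.assignments().to_csv(path, index=False, float_format="%.12g")
        medoids = pd.DataFrame({
            "cluster": [int(self.labels[i]) for i in self.medoid_indices],
            "medoid": self.medoid_ids,
        })
        medoids.to_csv(path.with_name(path.stem + "_medoids.csv"), index=False)


def standardize(
    means: pd.DataFrame,
    traits: Sequence[str],
    experiment: str,
    treatment: str = "D",
    units: Iterable[str] | None = None,
) -> FeatureMatrix:
    """Z-score genotype means within one experiment and treatment.

    Each trait column is centered on its mean and divided by its n−1 SD over
    the included units.  Units missing any selected trait are excluded (and
    listed); traits constant across units carry no clustering information
    and are dropped with a warning.
    """
    sub = means[(means["experiment"] == experiment) & (means["treatment"] == treatment)
                & (means["trait"].isin(traits))]
    wide = sub.pivot_table(index="genotype", columns="trait", values="mean", aggfunc="first")
    wide = wide.reindex(columns=[t for t in traits if t in wide.columns])
    if units is not None:
        wide = wide[wide.index.isin(set(units))]
    complete = wide.dropna()
    excluded = sorted(set(wide.index) - set(complete.index))
    if excluded:
        warnings.warn(f"{len(excluded)} unit(s) excluded for missing traits: {excluded}",
                      UserWarning, stacklevel=2)
    centers = complete.mean()
    scales = complete.std(ddof=1)
    constant = scales[scales == 0].index.tolist()
    if constant:
        warnings.warn(f"constant trait column(s) dropped: {constant}", UserWarning, stacklevel=2)
        complete = complete.drop(columns=constant)
        centers = centers.drop(constant)
        scales = scales.drop(constant)
    Z = (complete - centers) / scales
    return FeatureMatrix(X=Z, centers=centers, scales=scales, excluded_units=excluded,
                         dropped_traits=constant, experiment=experiment, treatment=treatment)


def _as_array(X) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def _unit_ids(X, n: int) -> list[str]:
    if isinstance(X, FeatureMatrix):
        return X.unit_ids
    return [str(i) for i in range(n)]


def dissimilarity_matrix(X, metric: str = "euclidean") -> np.ndarray:
    A = _as_array(X)
    diff = A[:, None, :] - A[None, :, :]
    if metric == "euclidean":
        return np.sqrt((diff**2).sum(axis=2))
    if metric == "manhattan":
        return np.abs(diff).sum(axis=2)
    raise ValueError(f"unknown metric {metric!r}")


def _assign(D: np.ndarray, medoids: list[int]) -> tuple[np.ndarray, float]:
    sub = D[:, medoids]                      # n × k
    nearest = sub.argmin(axis=1)             # ties -> lowest medoid position
    cost = float(sub[np.arange(len(D)), nearest].sum())
    return nearest, cost


def pam_fit(X, k: int, metric: str = "euclidean", max_iter: int | None = None) -> ClusterModel:
    """Deterministic PAM: greedy BUILD, then steepest-descent SWAP.

    BUILD seeds the first medoid as the point minimizing total dissimilarity
    and adds each further medoid to maximize the cost decrease.  SWAP then
    repeatedly evaluates every (medoid, non-medoid) exchange and applies the
    single best strictly cost-decreasing one until no exchange improves.
    No randomness anywhere; ties break on the lowest point index.

    Cost is the sum of dissimilarities of every unit to its nearest medoid.
    """
    D = dissimilarity_matrix(X, metric=metric)
    n = len(D)
    if not 2 <= k < n:
        raise ValueError(f"k must satisfy 2 <= k < n (k={k}, n={n})")
    if max_iter is None:
        max_iter = 20 * n * k  # generous bound; SWAP provably terminates earlier

    # BUILD
    medoids = [int(D.sum(axis=1).argmin())]
    while len(medoids) < k:
        nearest_d = D[:, medoids].min(axis=1)
        gains = np.maximum(nearest_d[None, :] - D, 0.0).sum(axis=1)  # gain of each candidate
        gains[medoids] = -np.inf
        medoids.append(int(gains.argmax()))

    # SWAP — steepest descent, single best swap per iteration
    _, cost = _assign(D, medoids)
    for _ in range(max_iter):
        best_delta, best_swap = 0.0, None
        medoid_set = set(medoids)
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoid_set:
                    continue
                trial = medoids.copy()
                trial[mi] = h
                _, trial_cost = _assign(D, trial)
                delta = trial_cost - cost
                if delta < best_delta - 1e-12:
                    best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
        cost += best_delta
    medoids = sorted(medoids)
    nearest, cost = _assign(D, medoids)
    ids = _unit_ids(X, n)
    return ClusterModel(
        k=k,
        medoid_indices=medoids,
        medoid_ids=[ids[m] for m in medoids],
        labels=nearest.astype(int),
        unit_ids=ids,
        total_cost=cost,
    )


def silhouette(X, model: ClusterModel, metric: str = "euclidean") -> tuple[np.ndarray, float]:
    """Silhouette widths s(i) = (b − a)/max(a, b) and their average.

    a(i) is the mean dissimilarity to the unit's own cluster (self excluded),
    b(i) the smallest mean dissimilarity to any other cluster.  Units in
    singleton clusters get s = 0 by convention; if a = b = 0 (coincident
    points) s = 0 as well.  Values always lie in [−1, 1].
    """
    D = dissimilarity_matrix(X, metric=metric)
    labels = model.labels
    n = len(labels)
    clusters = {c: np.flatnonzero(labels == c) for c in np.unique(labels)}
    s = np.zeros(n)
    if len(clusters) == 1:  # degenerate partition (e.g. coincident points): s = 0
        model.silhouette_values = s
        model.avg_silhouette = 0.0
        return s, 0.0
    for i in range(n):
        own = clusters[labels[i]]
        if len(own) == 1:
            s[i] = 0.0
            continue
        a = D[i, own[own != i]].mean()
        b = min(D[i, members].mean() for c, members in clusters.items() if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    model.silhouette_values = s
    model.avg_silhouette = float(s.mean())
    return s, float(s.mean())


def within_cluster_ss(X, model: ClusterModel, metric: str = "euclidean") -> float:
    """Sum over units of squared dissimilarity to the assigned medoid."""
    D = dissimilarity_matrix(X, metric=metric)
    med = np.array(model.medoid_indices)
    return float((D[np.arange(len(D)), med[model.labels]] ** 2).sum())


def choose_k(
    X,
    k_range: Iterable[int] = range(2, 9),
    metric: str = "euclidean",
) -> ClusterModel:
    """Fit PAM across k and select the k with greatest average silhouette.

    Ties go to the smaller k.  The within-cluster sum-of-squares-to-medoid
    curve is recorded alongside for elbow inspection but never decides.
    Returns the refitted model at the selected k with per-k diagnostics
    attached.
    """
    ks = sorted(k_range)
    n = len(_as_array(X))
    ks = [k for k in ks if 2 <= k < n]
    if not ks:
        raise ValueError("no feasible k in range")
    avg_sil_by_k: dict[int, float] = {}
    wss_by_k: dict[int, float] = {}
    models: dict[int, ClusterModel] = {}
    for k in ks:
        model = pam_fit(X, k, metric=metric)
        _, avg = silhouette(X, model, metric=metric)
        avg_sil_by_k[k] = avg
        wss_by_k[k] = within_cluster_ss(X, model, metric=metric)
        models[k] = model
    selected = max(ks, key=lambda k: (avg_sil_by_k[k], -k))
    best = models[selected]
    best.avg_sil_by_k = avg_sil_by_k
    best.wss_by_k = wss_by_k
    return best


def pca_scores(X) -> tuple[pd.DataFrame, np.ndarray]:
    """First two principal-component scores and explained-variance fractions.

    Computed from the SVD of the column-centered matrix.  Sign convention:
    within each component the largest-magnitude loading is made positive, so
    scores are reproducible across platforms.
    """
    A = _as_array(X)
    n = len(A)
    if n < 3:
        raise ValueError("PCA projection needs at least 3 units")
    centered = A - A.mean(axis=0)
    U, S, Vt = np.linalg.svd(centered, full_matrices=False)
    for j in range(len(S)):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total = (S**2).sum()
    explained = (S**2) / total if total > 0 else np.zeros_like(S)
    ncomp = min(2, len(S))
    scores = pd.DataFrame(
        U[:, :ncomp] * S[:ncomp],
        index=_unit_ids(X, n),
        columns=[f"PC{j + 1}" for j in range(ncomp)],
    )
    return scores, explained[:ncomp]


def canonicalize_labels(model: ClusterModel, biomass: pd.Series | None = None) -> ClusterModel:
    """Renumber clusters for order-stable output.

    When a biomass series (unit → value) is given, clusters are ordered by
    descending cluster-mean biomass so cluster 1 is always the best-
    performing; otherwise by medoid index.  Labels become 1-based.
    """
    old = np.unique(model.labels)
    if biomass is not None:
        bm = pd.Series(biomass)
        keyfun = lambda c: -bm.reindex(
            [model.unit_ids[i] for i in np.flatnonzero(model.labels == c)]
        ).mean()
    else:
        keyfun = lambda c: model.medoid_indices[c]
    order = sorted(old, key=keyfun)
    remap = {c: rank + 1 for rank, c in enumerate(order)}
    model.labels = np.array([remap[c] for c in model.labels])
    med_order = sorted(range(len(model.medoid_indices)), key=lambda j: remap[j])
    model.medoid_indices = [model.medoid_indices[j] for j in med_order]
    model.medoid_ids = [model.medoid_ids[j] for j in med_order]
    return model
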