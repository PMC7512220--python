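"""Sqrt/Pareto-scaled PCA and case-subgroup selection.

The stratification stage square-root transforms the replicate-averaged
intensities, Pareto-scales each protein (mean-centring followed by division by
the square root of the standard deviation — a standard compromise between no
scaling and unit variance for MS data), and decomposes the resulting
sample x protein matrix by SVD.  Subgroup selection replaces the visual
inspection of the score plot by a deterministic two-means partition of the
scores on chosen components, initialised at the two extreme-PC2 samples; the
cluster holding the majority of controls is "control-like" and any cases in
it are excluded from the signal subgroup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .errors import (
    DegenerateClusteringError,
    UnstableClusteringWarning,
    ZeroVarianceWarning,
)
from .quantify import ProteinMatrix

__all__ = ["PCAModel", "SubgroupAssignment", "sqrt_pareto_pca", "select_subgroup"]

#: minimum mean silhouette width for a two-cluster partition to be considered
#: supported by the score geometry rather than an artefact of forcing k=2;
#: follows the standard silhouette interpretation bands in which values above
#: 0.5 indicate reasonable structure while a forced split of an unstructured
#: point cloud typically lands near 0.3
SILHOUETTE_STABLE = 0.5


@dataclass
class PCAModel:
    """A fitted Sqrt/Pareto PCA.

    ``center`` and ``scale`` are per-protein vectors on the transformed
    (square-root) scale over the retained (non-constant) proteins;
    ``loadings`` is protein x component, ``scores`` sample x component, and
    ``explained_pct`` the percentage of total transformed-scaled variance per
    retained component (non-increasing).  The deterministic sign convention
    makes the largest-|loading| entry of each component positive.
    """

    sample_ids: list
    used_protein_ids: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_pct: np.ndarray
    sqrt_transform: bool = True
    pareto: bool = True
    dropped_protein_ids: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, index=self.sample_ids, columns=cols)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, index=self.used_protein_ids, columns=cols)

    def transform(self, matrix: ProteinMatrix) -> np.ndarray:
        """Project new samples with the training transform/centre/scale."""
        X = matrix.data.loc[self.used_protein_ids].to_numpy(float).T
        if self.sqrt_transform:
            X = np.sqrt(X)
        return ((X - self.center) / self.scale) @ self.loadings

    def reconstruct(self) -> np.ndarray:
        """Inverse-project the scores back to the transformed-scaled space."""
        return self.scores @ self.loadings.T


def sqrt_pareto_pca(
    matrix: ProteinMatrix,
    n_components: int | None = None,
    sqrt_transform: bool = True,
    pareto: bool = True,
) -> PCAModel:
    """Fit PCA on the Sqrt/Pareto-transformed averaged matrix.

    Proteins with zero variance after the square-root transform cannot be
    Pareto-scaled and are dropped from the decomposition with a warning (they
    remain in the input matrix untouched).
    """
    if matrix.stage != "averaged":
        raise ValueError(f"expected a stage='averaged' matrix, got {matrix.stage!r}")
    n_samples = matrix.data.shape[1]
    if n_samples < 2:
        raise ValueError("PCA needs at least 2 samples")

    X = matrix.data.to_numpy(float).T  # samples x proteins
    if sqrt_transform:
        X = np.sqrt(X)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [p for p, k in zip(matrix.data.index, keep) if not k]
        warnings.warn(
            f"{len(dropped)} zero-variance protein(s) dropped from PCA",
            ZeroVarianceWarning,
            stacklevel=2,
        )
    else:
        dropped = []
    used = [p for p, k in zip(matrix.data.index, keep) if k]
    X = X[:, keep]
    center = X.mean(axis=0)
    scale = np.sqrt(sd[keep]) if pareto else np.ones(keep.sum())
    Xs = (X - center) / scale

    U, s, Vt = np.linalg.svd(Xs, full_matrices=False)
    total_ss = float((s**2).sum())
    max_k = min(n_samples - 1, len(used))
    k = max_k if n_components is None else int(n_components)
    if not (1 <= k <= max_k):
        raise ValueError(
            f"n_components must lie in [1, {max_k}] for this matrix, got {k}"
        )

    loadings = Vt[:k].T
    scores = U[:, :k] * s[:k]
    explained = 100.0 * (s[:k] ** 2) / total_ss if total_ss > 0 else np.zeros(k)

    # sign convention: largest-|loading| entry of each component is positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1

    return PCAModel(
        sample_ids=list(matrix.data.columns),
        used_protein_ids=used,
        center=center,
        scale=scale,
        loadings=loadings,
        scores=scores,
        explained_pct=explained,
        sqrt_transform=sqrt_transform,
        pareto=pareto,
        dropped_protein_ids=dropped,
    )


@dataclass
class SubgroupAssignment:
    """Partition of the case samples into signal subgroup vs control-like."""

    core_case_ids: list
    excluded_case_ids: list
    method_record: dict
    stable: bool
    silhouette: float


def _lloyd(points: np.ndarray, c: np.ndarray) -> np.ndarray:
    labels = -np.ones(len(points), dtype=int)
    for _ in range(200):
        d0 = np.linalg.norm(points - c[0], axis=1)
        d1 = np.linalg.norm(points - c[1], axis=1)
        new = (d1 < d0).astype(int)  # ties -> cluster 0
        if (new == labels).all():
            break
        labels = new
        for j in (0, 1):
            if (labels == j).any():
                c = c.copy()
                c[j] = points[labels == j].mean(axis=0)
    return labels


def _within_ss(points: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for j in (0, 1):
        grp = points[labels == j]
        if len(grp):
            ss += float(((grp - grp.mean(axis=0)) ** 2).sum())
    return ss


def _two_means(points: np.ndarray) -> np.ndarray:
    """Deterministic 2-means on rows of ``points``.

    Lloyd iterations are run from every distinct sample pair as initial
    centroids and the partition with the smallest within-cluster sum of
    squares is kept (single-start Lloyd is sensitive to its initialisation;
    with the ~20 samples of a cohort, all-pairs restarts are cheap and make
    the result a deterministic, near-exact optimiser of the 2-means
    objective).  Distance ties assign to cluster 0; equal-score partitions
    keep the first in pair order.
    """
    if np.allclose(points, points[0]):
        raise DegenerateClusteringError("all score coordinates identical")
    n = len(points)
    best_labels, best_ss = None, np.inf
    for i in range(n):
        for j in range(i + 1, n):
            if np.allclose(points[i], points[j]):
                continue
            labels = _lloyd(points, np.vstack([points[i], points[j]]))
            if len(set(labels)) < 2:
                continue
            ss = _within_ss(points, labels)
            if ss < best_ss - 1e-12:
                best_ss, best_labels = ss, labels
    if best_labels is None:
        raise DegenerateClusteringError("no non-trivial two-cluster partition found")
    return best_labels


def select_subgroup(
    model: PCAModel,
    samples: pd.DataFrame,
    components: tuple[int, ...] = (1, 2),
) -> SubgroupAssignment:
    """Split cases into the signal subgroup and control-co-clustering cases.

    ``components`` are 1-based principal-component indices.  The two-means
    partition of the scores is computed over all samples; the cluster with the
    majority of controls is labelled control-like, and case samples falling in
    it are excluded.  A mean silhouette width below ``SILHOUETTE_STABLE``
    flags the assignment as unstable (not interpretable).
    """
    idx = [c - 1 for c in components]
    if min(idx) < 0 or max(idx) >= model.n_components:
        raise ValueError(f"components {components} out of range for k={model.n_components}")
    pts = model.scores[:, idx]
    labels = _two_means(pts)

    grp = dict(zip(samples["sample_id"], samples["group"]))
    groups = np.array([grp[s] for s in model.sample_ids])
    n_ctrl0 = int(((labels == 0) & (groups == "control")).sum())
    n_ctrl1 = int(((labels == 1) & (groups == "control")).sum())
    control_like = 0 if n_ctrl0 >= n_ctrl1 else 1

    case_ids = [s for s in model.sample_ids if grp[s] == "case"]
    excluded = [
        s
        for s, lab in zip(model.sample_ids, labels)
        if grp[s] == "case" and lab == control_like
    ]
    core = [s for s in case_ids if s not in excluded]

    if len(set(labels)) == 2:
        sil = float(silhouette_score(pts, labels))
    else:
        sil = -1.0
    stable = sil >= SILHOUETTE_STABLE
    if not stable:
        warnings.warn(
            f"two-cluster partition weakly supported (silhouette {sil:.3f}); "
            "subgroup assignment should not be interpreted",
            category=UnstableClusteringWarning,
            stacklevel=2,
        )
    return SubgroupAssignment(
        core_case_ids=core,
        excluded_case_ids=excluded,
        method_record={
            "rule": "deterministic 2-means on PCA scores",
            "components": list(components),
            "init": "maximally distant sample pair in the score plane",
            "silhouette_threshold": SILHOUETTE_STABLE,
        },
        stable=stable,
        silhouette=sil,
    )
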