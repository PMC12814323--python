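"""Shared-basis backbone PCA and microstate clustering.

One PCA model is fitted to the pooled, superposed backbone coordinates of
every ensemble, so per-frame scores are directly comparable across
ensembles. Each ensemble is then clustered into microstates (k-means on
the first few PCs, k chosen by silhouette), and cluster populations,
medoid frames, PC histograms and cluster-center RMSDs are derived.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._geom import pairwise_rmsd
from .trajio import BackboneMatrix

__all__ = [
    "PCAModel",
    "ProjectedScores",
    "ClusterAssignment",
    "fit_shared_pca",
    "project",
    "cluster_ensemble",
    "medoid_frame",
    "histogram2d",
    "oblique_histogram",
    "cluster_center_rmsd",
]


@dataclass
class PCAModel:
    """Shared mean + orthonormal components over backbone coordinates."""

    mean: np.ndarray  # (n_coordinates,)
    components: np.ndarray  # (n_components, n_coordinates), row-orthonormal
    explained_variance: np.ndarray  # non-increasing

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(len(self.components)), atol=1e-8):
            raise ValueError("components are not row-orthonormal")
        if np.any(np.diff(self.explained_variance) > 1e-9):
            raise ValueError("explained variances must be non-increasing")


@dataclass
class ProjectedScores:
    """Per-frame PC scores with (ensemble, replica, frame) labels."""

    scores: np.ndarray  # (n_frames_total, n_components)
    labels: pd.DataFrame  # columns: label, replica, frame

    def __post_init__(self) -> None:
        if len(self.labels) != self.scores.shape[0]:
            raise ValueError("labels/scores row mismatch")

    def subset(self, label: str) -> "ProjectedScores":
        mask = (self.labels["label"] == label).to_numpy()
        if not mask.any():
            raise KeyError(f"no frames labeled {label!r}")
        return ProjectedScores(self.scores[mask], self.labels[mask].reset_index(drop=True))


@dataclass
class ClusterAssignment:
    """Microstate partition of one ensemble's frames in PC space."""

    label: str
    k: int
    assignments: np.ndarray  # per-frame cluster index, canonical order
    centers: np.ndarray  # (k, n_components) in full PC space
    populations: np.ndarray  # percent per cluster, sums to 100
    medoids: list[tuple[int, int]]  # per-cluster (replica id, frame index)
    n_dims: int  # PCs used for the partition
    frame_labels: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if abs(self.populations.sum() - 100.0) > 1e-9:
            raise ValueError("populations must sum to 100%")


def fit_shared_pca(pooled: BackboneMatrix, n_components: int = 20) -> PCAModel:
    """Fit one PCA to the pooled superposed backbone matrix.

    Deterministic up to component sign; the sign is fixed by making each
    component's largest-magnitude entry positive.
    """
    x = pooled.frame_rows
    if x.shape[0] < 2:
        raise ValueError("need at least 2 frames to fit a PCA")
    n_components = min(n_components, x.shape[0] - 1, x.shape[1])
    p = PCA(n_components=n_components, svd_solver="full")
    p.fit(x)
    comps = p.components_.copy()
    flip = np.sign(comps[np.arange(len(comps)), np.argmax(np.abs(comps), axis=1)])
    comps *= flip[:, None]
    return PCAModel(
        mean=p.mean_,
        components=comps,
        explained_variance=p.explained_variance_,
    )


def project(model: PCAModel, matrix: BackboneMatrix) -> ProjectedScores:
    """Project frames onto the shared basis: (x - mean) @ components.T."""
    if matrix.frame_rows.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"matrix has {matrix.frame_rows.shape[1]} columns, model expects "
            f"{model.mean.shape[0]}"
        )
    scores = (matrix.frame_rows - model.mean) @ model.components.T
    return ProjectedScores(scores=scores, labels=matrix.labels.copy())


def cluster_ensemble(
    scores: ProjectedScores,
    k_range: tuple[int, ...] = (4, 5, 6),
    n_dims: int = 5,
    seed: int = 0,
    silhouette_sample: int = 2000,
) -> ClusterAssignment:
    """Partition one ensemble's frames into microstates.

    K-means (10 restarts, seeded) on the first ``n_dims`` PCs; k is chosen
    within ``k_range`` by the mean silhouette score (subsampled, seeded,
    for large ensembles). Clusters are canonically ordered by descending
    population; centers are reported in the full PC space as cluster means.
    """
    labels_unique = scores.labels["label"].unique()
    if len(labels_unique) != 1:
        raise ValueError("cluster_ensemble expects frames of exactly one ensemble")
    if any(k < 1 or k > 12 for k in k_range):
        raise ValueError("k_range must lie within [1, 12]")
    x = scores.scores[:, : max(n_dims, 2)]
    n = x.shape[0]
    if n < max(k_range):
        raise ValueError(f"fewer frames ({n}) than clusters requested ({max(k_range)})")

    best = None
    for k in sorted(k_range):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        assign = km.fit_predict(x)
        if len(k_range) == 1:
            score = 0.0
        elif k == 1:
            score = -np.inf
        else:
            score = silhouette_score(
                x,
                assign,
                sample_size=min(silhouette_sample, n),
                random_state=seed,
            )
        if best is None or score > best[0]:
            best = (score, k, assign)
    _, k, assign = best

    # canonical order: descending population, ties by center PC0 (both
    # invariant under frame permutation)
    counts = np.bincount(assign, minlength=k)
    raw_centers = np.stack(
        [
            scores.scores[assign == c].mean(axis=0)
            if counts[c]
            else np.full(scores.scores.shape[1], np.inf)
            for c in range(k)
        ]
    )
    order = np.lexsort((raw_centers[:, 0], -counts))
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    assign = relabel[assign]
    counts = counts[order]
    centers = raw_centers[order]

    populations = 100.0 * counts / counts.sum()

    out = ClusterAssignment(
        label=str(labels_unique[0]),
        k=k,
        assignments=assign,
        centers=centers,
        populations=populations,
        medoids=[(-1, -1)] * k,
        n_dims=n_dims,
        frame_labels=scores.labels.copy(),
    )
    out.medoids = medoid_frame(out, scores)
    return out


def medoid_frame(
    assignment: ClusterAssignment, scores: ProjectedScores
) -> list[tuple[int, int]]:
    """Per-cluster frame nearest its center in the first n_dims PCs.

    Ties are broken toward the lowest (replica, frame) index.
    """
    if len(assignment.assignments) != scores.scores.shape[0]:
        raise ValueError("assignment and scores are inconsistent")
    d = assignment.n_dims
    reps = scores.labels["replica"].to_numpy()
    frames = scores.labels["frame"].to_numpy()
    medoids = []
    for c in range(assignment.k):
        idx = np.flatnonzero(assignment.assignments == c)
        dist = np.linalg.norm(
            scores.scores[idx, :d] - assignment.centers[c, :d], axis=1
        )
        # lexicographic tie-break: distance, then replica, then frame
        order = np.lexsort((frames[idx], reps[idx], np.round(dist, 12)))
        best = idx[order[0]]
        medoids.append((int(reps[best]), int(frames[best])))
    return medoids


def shared_edges(
    scores_list: list[ProjectedScores], pc_pair: tuple[int, int] = (0, 1), bins: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """Common bin edges over the pooled score range, so per-ensemble
    histogram panels are directly comparable."""
    i, j = pc_pair
    all_x = np.concatenate([s.scores[:, i] for s in scores_list])
    all_y = np.concatenate([s.scores[:, j] for s in scores_list])
    return (
        np.linspace(all_x.min(), all_x.max(), bins + 1),
        np.linspace(all_y.min(), all_y.max(), bins + 1),
    )


def histogram2d(
    scores: ProjectedScores,
    pc_pair: tuple[int, int] = (0, 1),
    bins: int | tuple[np.ndarray, np.ndarray] = 100,
    normalized: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of a PC pair. Pass shared edges (from
    ``shared_edges``) to make panels comparable across ensembles."""
    i, j = pc_pair
    if scores.scores.shape[0] == 0:
        raise ValueError("empty score selection")
    h, ex, ey = np.histogram2d(scores.scores[:, i], scores.scores[:, j], bins=bins)
    if normalized:
        h = h / h.sum()
    return h, ex, ey


def oblique_histogram(
    scores: ProjectedScores,
    angle_deg: float = 60.0,
    bins: int | np.ndarray = 100,
    pc_pair: tuple[int, int] = (0, 1),
) -> tuple[np.ndarray, np.ndarray]:
    """1-D histogram along the axis at ``angle_deg`` (counterclockwise
    from PC0) in the PC0-PC1 plane; visualizes population shifts that a
    single PC would blur."""
    theta = np.radians(angle_deg)
    axis = np.array([np.cos(theta), np.sin(theta)])
    proj = scores.scores[:, list(pc_pair)] @ axis
    return np.histogram(proj, bins=bins)


def cluster_center_rmsd(
    assignments: list[ClusterAssignment], model: PCAModel
) -> tuple[np.ndarray, list[tuple[str, int]]]:
    """Pairwise backbone RMSD between all cluster centers of all ensembles.

    Each center is back-projected to coordinate space (mean + center @
    components) and compared after rigid-body fitting. Returns the
    symmetric matrix plus (ensemble label, cluster) row names.
    """
    names: list[tuple[str, int]] = []
    coords = []
    for a in assignments:
        for c in range(a.k):
            names.append((a.label, c))
            flat = model.mean + a.centers[c] @ model.components
            coords.append(flat.reshape(-1, 3))
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pairwise_rmsd(coords[i], coords[j])
    return mat, names
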