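"""Conformational clustering of trajectory frames.

The distance metric is the best-fit mass-weighted backbone RMSD between
frames; hierarchical agglomerative clustering merges until the minimum
inter-cluster linkage distance exceeds the cutoff (~2 Å by convention for
protein backbones).  Average linkage is the default, matching the common
trajectory-clustering default; single and complete linkage are available.
The representative frame of a cluster is its medoid: the member minimizing
the sum of distances to all other members (ties broken by lowest frame
index), and the "most representative cluster" is simply the largest one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import kabsch_fit, select_backbone
from .io import Topology, Trajectory

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "ClusterError",
    "pairwise_rmsd_matrix",
    "agglomerative_cluster",
    "representative_frame",
]


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class ClusterConfig:
    cutoff: float = 2.0                  # Å
    linkage: str = "average"             # average | single | complete
    mass_weighted: bool = True
    selection: str = "backbone"          # backbone | heavy | all

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ClusterError("cutoff must be > 0")
        if self.linkage not in ("average", "single", "complete"):
            raise ClusterError(f"unknown linkage {self.linkage!r}")


@dataclass
class ClusterResult:
    labels: np.ndarray          # per-frame cluster id, 0 = largest cluster
    sizes: np.ndarray           # per-cluster frame counts, descending
    representatives: np.ndarray  # per-cluster frame index (medoid)
    merge_heights: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def frames_of(self, cluster: int) -> np.ndarray:
        return np.nonzero(self.labels == cluster)[0]

    def summary(self) -> dict:
        return {"n_clusters": int(self.n_clusters),
                "sizes": [int(s) for s in self.sizes],
                "representatives": [int(r) for r in self.representatives]}


def _selection_indices(topology: Topology, config: ClusterConfig) -> np.ndarray:
    if config.selection == "backbone":
        return select_backbone(topology)
    if config.selection == "heavy":
        return np.array([i for i, a in enumerate(topology.atoms)
                         if a.element != "H"], dtype=int)
    if config.selection == "all":
        return np.arange(topology.n_atoms)
    raise ClusterError(f"unknown selection {config.selection!r}")


def pairwise_rmsd_matrix(trajectory: Trajectory, topology: Topology,
                         config: ClusterConfig = ClusterConfig()
                         ) -> np.ndarray:
    """Symmetric matrix of best-fit (mass-weighted) RMSDs between frames."""
    frames = trajectory.windowed
    n = frames.shape[0]
    if n < 2:
        raise ClusterError("pairwise RMSD requires at least 2 frames")
    sel = _selection_indices(topology, config)
    if sel.size == 0:
        raise ClusterError(f"empty selection {config.selection!r}")
    sub = frames[:, sel]
    weights = topology.masses[sel] if config.mass_weighted else None
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = kabsch_fit(sub[j], sub[i], weights).rmsd
    return out


def agglomerative_cluster(dist_matrix: np.ndarray,
                          config: ClusterConfig = ClusterConfig()
                          ) -> ClusterResult:
    """Hierarchical agglomerative clustering of a distance matrix.

    Merging proceeds under ``config.linkage`` until every remaining
    inter-cluster distance exceeds ``config.cutoff``; cluster ids are
    assigned by descending size (ties by lowest first-frame index).
    """
    d = np.asarray(dist_matrix, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ClusterError("distance matrix must be square")
    if np.abs(d - d.T).max() > 1e-9:
        raise ClusterError("distance matrix is not symmetric (beyond 1e-9)")
    if np.any(d < 0):
        raise ClusterError("distance matrix has negative entries")
    n = d.shape[0]
    if n == 1:
        return ClusterResult(np.zeros(1, dtype=int), np.array([1]),
                             np.array([0]))
    z = linkage(squareform(d, checks=False), method=config.linkage)
    raw = fcluster(z, t=config.cutoff, criterion="distance")
    return _relabel(raw - 1, d, merge_heights=z[:, 2])


def _relabel(raw_labels: np.ndarray, dist_matrix: np.ndarray,
             merge_heights: np.ndarray | None = None) -> ClusterResult:
    ids = np.unique(raw_labels)
    order = sorted(
        ids,
        key=lambda c: (-int((raw_labels == c).sum()),
                       int(np.nonzero(raw_labels == c)[0][0])))
    labels = np.empty_like(raw_labels)
    for new, old in enumerate(order):
        labels[raw_labels == old] = new
    sizes = np.array([(labels == c).sum() for c in range(len(order))])
    reps = representative_frame(labels, dist_matrix)
    return ClusterResult(labels, sizes, reps,
                         merge_heights if merge_heights is not None
                         else np.array([]))


def representative_frame(labels: np.ndarray,
                         dist_matrix: np.ndarray) -> np.ndarray:
    """Medoid frame index per cluster.

    The representative minimizes the summed distance to all frames of its
    cluster; ties resolve to the lowest frame index (``argmin`` semantics).
    """
    labels = np.asarray(labels)
    d = np.asarray(dist_matrix)
    if labels.shape[0] != d.shape[0]:
        raise ClusterError("labels inconsistent with matrix dimension")
    reps = []
    for c in range(int(labels.max()) + 1):
        members = np.nonzero(labels == c)[0]
        if members.size == 0:
            raise ClusterError(f"cluster {c} has no members")
        sums = d[np.ix_(members, members)].sum(axis=1)
        reps.append(int(members[int(np.argmin(sums))]))
    return np.array(reps, dtype=int)
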