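"""Hierarchical agglomerative clustering on pairwise-RMSD matrices.

Frames are superposed once onto a common reference using the fit selection
(e.g. core-histone helical CA atoms) and the pairwise RMSD is then taken on
the measure selection (e.g. linker-histone helical CA atoms) between the
aligned frames.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .core_io import AtomSelection, StructureFrame, Trajectory
from .errors import MatrixValidityError, ParameterError
from .geometry import superpose


@dataclass
class ClusterResult:
    assignments: np.ndarray  # per-frame cluster id, 0-based, ordered by size
    populations: np.ndarray  # fraction per cluster, descending
    representatives: np.ndarray  # medoid frame index per cluster
    cutoff: float
    linkage: str

    @property
    def n_clusters(self) -> int:
        return self.populations.size


def pairwise_rmsd_matrix(
    traj: Trajectory,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection,
    reference: StructureFrame | None = None,
) -> np.ndarray:
    """Symmetric matrix of measure-selection RMSDs between aligned frames."""
    if traj.n_frames < 2:
        raise ParameterError("need >= 2 frames for a pairwise matrix")
    ref = reference.coords if reference is not None else traj.frames[0]
    fit_idx = fit_sel.indices
    meas_idx = measure_sel.indices
    aligned = np.stack(
        [
            superpose(traj.frames[f], fit_idx, ref, fit_idx)[meas_idx]
            for f in range(traj.n_frames)
        ]
    )
    n = traj.n_frames
    # (n, n) RMSD from pairwise squared differences
    flat = aligned.reshape(n, -1)
    sq = ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(axis=2)
    matrix = np.sqrt(sq / meas_idx.size)
    np.fill_diagonal(matrix, 0.0)
    return matrix


def _validate_matrix(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise MatrixValidityError(f"matrix must be square, got {m.shape}")
    if not np.allclose(m, m.T, atol=1e-8):
        raise MatrixValidityError("matrix is not symmetric")
    if np.any(m < 0):
        raise MatrixValidityError("matrix has negative entries")
    if not np.allclose(np.diag(m), 0.0, atol=1e-8):
        raise MatrixValidityError("matrix diagonal is not zero")
    return m


def hierarchical_cluster(
    matrix: np.ndarray, cutoff: float = 2.0, linkage_method: str = "average"
) -> ClusterResult:
    """Average-linkage agglomeration cut at ``cutoff``.

    Cluster ids are relabeled by population (0 = largest); medoids minimize
    the summed in-cluster distance with lowest-frame-index tie-breaking.
    """
    m = _validate_matrix(matrix)
    if cutoff <= 0:
        raise ParameterError("cutoff must be > 0")
    n = m.shape[0]
    condensed = squareform(m, checks=False)
    z = linkage(condensed, method=linkage_method)
    raw = fcluster(z, t=cutoff, criterion="distance")
    # Relabel by descending population; ties broken by lowest member index.
    labels = np.unique(raw)
    sizes = np.array([(raw == lab).sum() for lab in labels])
    first_member = np.array([int(np.argmax(raw == lab)) for lab in labels])
    order = np.lexsort((first_member, -sizes))
    remap = {int(labels[old]): new for new, old in enumerate(order)}
    assignments = np.array([remap[int(lab)] for lab in raw])
    populations = np.array(
        [(assignments == c).sum() / n for c in range(labels.size)]
    )
    representatives = np.empty(labels.size, dtype=int)
    for c in range(labels.size):
        members = np.flatnonzero(assignments == c)
        sums = m[np.ix_(members, members)].sum(axis=1)
        representatives[c] = members[int(np.argmin(sums))]  # argmin: lowest index tie
    return ClusterResult(
        assignments=assignments,
        populations=populations,
        representatives=representatives,
        cutoff=cutoff,
        linkage=linkage_method,
    )


def top_fraction(result: ClusterResult, fraction: float = 0.90) -> ClusterResult:
    """Smallest prefix of population-sorted clusters covering ``fraction``.

    Frames outside the retained clusters get assignment -1.
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    cumulative = np.cumsum(result.populations)
    keep = int(np.searchsorted(cumulative, fraction - 1e-12) + 1)
    keep = min(keep, result.n_clusters)
    assignments = np.where(result.assignments < keep, result.assignments, -1)
    return ClusterResult(
        assignments=assignments,
        populations=result.populations[:keep],
        representatives=result.representatives[:keep],
        cutoff=result.cutoff,
        linkage=result.linkage,
    )
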