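"""Distribution statistics over angle series: histograms, MI/NMI, KL.

Unit conventions: mutual information and entropies are reported in bits
(base-2 logs); KL divergence in nats (natural log).  Both are recorded in
result metadata.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyInputError, GridMismatchError, ParameterError
from .geometry import AngleSeries


@dataclass
class JointDistribution:
    x_edges: np.ndarray
    y_edges: np.ndarray
    P: np.ndarray  # normalized joint mass, shape (nx, ny)
    n_samples: int

    def __post_init__(self) -> None:
        self.x_edges = np.asarray(self.x_edges, float)
        self.y_edges = np.asarray(self.y_edges, float)
        self.P = np.asarray(self.P, float)
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(self.P < 0):
            raise ParameterError("joint mass must be non-negative")
        total = self.P.sum()
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(f"joint mass sums to {total}, not 1")


@dataclass
class MutualInformationResult:
    mi: float  # bits
    h_x: float  # bits
    h_y: float  # bits
    nmi: float  # dimensionless, [0, 1]
    units: str = "bits"


def histogram2d(
    x: AngleSeries | np.ndarray,
    y: AngleSeries | np.ndarray,
    bins: int,
    range_policy: str = "data",
    limits: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> JointDistribution:
    """Binned, mass-normalized joint distribution of two angle series.

    ``range_policy='fixed'`` with explicit ``limits`` is recommended when
    comparing systems (a shared grid is required for KL).
    """
    xv = np.asarray(x.values if isinstance(x, AngleSeries) else x, float)
    yv = np.asarray(y.values if isinstance(y, AngleSeries) else y, float)
    if xv.size == 0 or yv.size == 0:
        raise EmptyInputError("empty angle series")
    if xv.size != yv.size:
        raise ParameterError("series lengths differ")
    if bins < 2:
        raise ParameterError("bins must be >= 2")
    ok = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[ok], yv[ok]
    if range_policy == "fixed":
        if limits is None:
            raise ParameterError("range_policy='fixed' requires limits")
        rng = limits
    elif range_policy == "data":
        rng = None
    else:
        raise ParameterError(f"unknown range_policy {range_policy!r}")
    counts, xe, ye = np.histogram2d(xv, yv, bins=bins, range=rng)
    total = counts.sum()
    if total == 0:
        raise EmptyInputError("all samples fall outside the fixed range")
    return JointDistribution(xe, ye, counts / total, int(xv.size))


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(joint: JointDistribution) -> MutualInformationResult:
    """MI (bits) and NMI normalized by the geometric mean of the marginals.

    NMI is defined as 0 when either marginal entropy vanishes (a constant
    series carries no information to share).
    """
    p = joint.P
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = np.outer(px, py)
    nz = p > 0
    mi = float((p[nz] * np.log2(p[nz] / outer[nz])).sum())
    mi = max(mi, 0.0)  # guard tiny negative rounding
    h_x = _entropy_bits(px)
    h_y = _entropy_bits(py)
    denom = np.sqrt(h_x * h_y)
    nmi = mi / denom if denom > 0 else 0.0
    return MutualInformationResult(mi=mi, h_x=h_x, h_y=h_y, nmi=float(min(nmi, 1.0)))


def kl_divergence(
    p: np.ndarray | JointDistribution,
    q: np.ndarray | JointDistribution,
    regularization: float | None = None,
    n_samples: int | None = None,
) -> float:
    """KL divergence D(P||Q) in nats on a shared grid.

    ``p`` is the data distribution (e.g. chromatosome angles) and ``q`` the
    reference (nucleosome angles).  A pseudo-mass ``regularization`` is
    added to every cell of both distributions and they are renormalized, so
    the result is finite even when Q has empty cells.  The default is
    ``1/(10 * n_samples)`` per cell when a sample count is known, else 1e-10.
    """
    if isinstance(p, JointDistribution):
        if isinstance(q, JointDistribution):
            if p.P.shape != q.P.shape or not (
                np.allclose(p.x_edges, q.x_edges) and np.allclose(p.y_edges, q.y_edges)
            ):
                raise GridMismatchError("P and Q are binned on different grids")
        if n_samples is None:
            n_samples = p.n_samples
        p = p.P
    if isinstance(q, JointDistribution):
        q = q.P
    p = np.asarray(p, float).ravel()
    q = np.asarray(q, float).ravel()
    if p.shape != q.shape:
        raise GridMismatchError(f"shape mismatch {p.shape} vs {q.shape}")
    if regularization is None:
        regularization = 1.0 / (10.0 * n_samples) if n_samples else 1e-10
    if regularization < 0:
        raise ParameterError("regularization must be >= 0")
    if regularization > 0:
        p = p + regularization
        q = q + regularization
    p = p / p.sum()
    q = q / q.sum()
    nz = p > 0
    if np.any(q[nz] == 0):
        return float("inf")
    return float((p[nz] * np.log(p[nz] / q[nz])).sum())


def nmi_pair(
    x: AngleSeries | np.ndarray,
    y: AngleSeries | np.ndarray,
    bins: int = 50,
    limits: tuple | None = None,
) -> MutualInformationResult:
    """Convenience: histogram then MI/NMI in one call."""
    policy = "fixed" if limits is not None else "data"
    return mutual_information(histogram2d(x, y, bins, policy, limits))
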