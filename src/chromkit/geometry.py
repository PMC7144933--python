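"""Coordinate-derived observables.

Angle conventions
-----------------
* ``vector_angle`` is the unsigned angle in [0°, 180°].
* The nucleosomal plane is built from three points: the C1' centers of mass
  of the two DNA quadrants distal from the linker arms (p1, p2) and the C1'
  center of mass of the dyad base pair (p3).  The plane normal is
  ``unit((p1 - p3) x (p2 - p3))`` with its sign fixed to point away from the
  core-particle center of mass.
* β (out-of-plane) is the signed elevation of a linker-arm vector above the
  plane: positive on the +normal side, in (−90°, +90°].
* α (in-plane) is measured against the in-plane dyad direction
  ``ref = p3 − midpoint(p1, p2)``.  An arm whose in-plane projection is
  perpendicular to ``ref`` has α = 0; bending toward the dyad axis is
  positive, i.e. ``α = 90° − angle(projection, ref)``, signed in (−90°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core_io import AtomSelection, StructureFrame, Trajectory
from .errors import (
    DegenerateGeometryError,
    ParameterError,
    SelectionEmptyError,
    StructuralMismatchError,
)

ANGLE_LABELS = ("phi1", "phi2", "alpha_entry", "alpha_exit", "beta_entry", "beta_exit")


@dataclass
class AngleSeries:
    """Per-frame angle values in degrees; NaN marks undefined frames."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class PlaneFrame:
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    normal: np.ndarray

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-8:
            raise ParameterError("plane normal must be unit length")


@dataclass
class LinkerArmSpec:
    origin_selection: AtomSelection
    terminal_selection: AtomSelection
    side: str = "entry"

    def __post_init__(self) -> None:
        if len(self.origin_selection) == 0 or len(self.terminal_selection) == 0:
            raise SelectionEmptyError("linker-arm selections must be non-empty")


@dataclass
class ContactTable:
    """Residue-pair contact statistics over a trajectory."""

    pairs: pd.DataFrame  # residue_a, residue_b, frames_in_contact, fraction
    n_frames: int
    per_frame_totals: np.ndarray = field(default=None)

    def group_totals(self, groups: dict[str, set[int]], side: str = "a") -> pd.DataFrame:
        """Mean ± SD of per-frame summed contacts per residue group.

        ``groups`` maps a label (e.g. a secondary-structure element) to the
        residue indices it covers on side ``a`` of the pair table.
        """
        key = "residue_a" if side == "a" else "residue_b"
        rows = []
        for label, resids in groups.items():
            sub = self.pairs[self.pairs[key].isin(resids)]
            per_frame = np.zeros(self.n_frames)
            for counts in sub["frame_mask"]:
                per_frame += counts
            rows.append(
                {
                    "group": label,
                    "mean_contacts": float(per_frame.mean()),
                    "sd_contacts": float(per_frame.std(ddof=0)),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees in [0, 180]."""
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise DegenerateGeometryError("zero-length vector in vector_angle")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def center_of_mass(coords: np.ndarray, masses: np.ndarray | None = None) -> np.ndarray:
    coords = np.asarray(coords, float)
    if coords.size == 0:
        raise SelectionEmptyError("empty coordinate set for center of mass")
    if masses is None:
        return coords.mean(axis=0)
    masses = np.asarray(masses, float)
    return (coords * masses[:, None]).sum(axis=0) / masses.sum()


def principal_axis(coords: np.ndarray, orient: np.ndarray | None = None) -> np.ndarray:
    """Dominant principal axis of a coordinate set (unit vector).

    ``orient``: vector whose dot product with the axis is forced positive
    (used to orient helix axes N→C, with N-to-C taken as first-to-last atom).
    """
    coords = np.asarray(coords, float)
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("principal axis needs >= 3 atoms")
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    if orient is None:
        orient = coords[-1] - coords[0]
    if np.dot(axis, orient) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


# ---------------------------------------------------------------------------
# β-loop ϕ angles
# ---------------------------------------------------------------------------

def compute_phi_angles(
    traj: Trajectory,
    groups: dict[str, AtomSelection],
) -> tuple[AngleSeries, AngleSeries]:
    """Per-frame loop-orientation angles.

    ``groups`` must provide ``alpha1``, ``alpha3``, ``beta_loop`` and
    ``beta_sheet`` selections.  Per frame the loop vector runs from the
    alpha3 COM to the beta_loop COM; ``phi1`` is its angle to the alpha1
    principal axis, ``phi2`` to the beta_sheet principal axis.
    """
    for key in ("alpha1", "alpha3", "beta_loop", "beta_sheet"):
        if key not in groups:
            raise ParameterError(f"missing group {key!r}")
        if len(groups[key]) == 0:
            raise SelectionEmptyError(f"group {key!r} resolved to no atoms")
    masses = traj.topology.masses()
    phi1 = np.empty(traj.n_frames)
    phi2 = np.empty(traj.n_frames)
    ia1 = groups["alpha1"].indices
    ia3 = groups["alpha3"].indices
    ibl = groups["beta_loop"].indices
    ibs = groups["beta_sheet"].indices
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        v_loop = center_of_mass(xyz[ibl], masses[ibl]) - center_of_mass(
            xyz[ia3], masses[ia3]
        )
        phi1[f] = vector_angle(v_loop, principal_axis(xyz[ia1]))
        phi2[f] = vector_angle(v_loop, principal_axis(xyz[ibs]))
    return AngleSeries("phi1", phi1), AngleSeries("phi2", phi2)


# ---------------------------------------------------------------------------
# Nucleosomal plane and linker-DNA α/β angles
# ---------------------------------------------------------------------------

@dataclass
class PlaneSpec:
    """Selections defining the nucleosomal plane."""

    quadrant_a: AtomSelection  # C1' atoms, first distal quadrant
    quadrant_b: AtomSelection  # C1' atoms, second distal quadrant
    dyad_pair: AtomSelection  # C1' atoms of the dyad base pair
    core_reference: AtomSelection | None = None  # core-particle atoms for normal sign


def define_nucleosomal_plane(
    coords: np.ndarray,
    spec: PlaneSpec,
    masses: np.ndarray | None = None,
) -> PlaneFrame:
    """Build the plane for one frame; normal points away from the core COM."""
    if len(spec.quadrant_a) == 0 or len(spec.quadrant_b) == 0:
        raise SelectionEmptyError("distal quadrants must contain C1' atoms")
    if len(spec.dyad_pair) == 0:
        raise SelectionEmptyError("dyad pair selection is empty")

    def com(sel: AtomSelection) -> np.ndarray:
        m = masses[sel.indices] if masses is not None else None
        return center_of_mass(coords[sel.indices], m)

    p1, p2, p3 = com(spec.quadrant_a), com(spec.quadrant_b), com(spec.dyad_pair)
    cross = np.cross(p1 - p3, p2 - p3)
    norm = np.linalg.norm(cross)
    scale = max(np.linalg.norm(p1 - p3), np.linalg.norm(p2 - p3), 1.0)
    if norm < 1e-9 * scale * scale:
        raise DegenerateGeometryError("plane points are collinear")
    normal = cross / norm
    if spec.core_reference is not None and len(spec.core_reference) > 0:
        core_com = com(spec.core_reference)
        centroid = (p1 + p2 + p3) / 3.0
        if np.dot(normal, core_com - centroid) > 0:
            normal = -normal
    return PlaneFrame(p1, p2, p3, normal)


def _arm_angles(arm: np.ndarray, plane: PlaneFrame) -> tuple[float, float]:
    """Signed (alpha, beta) of one arm vector against one plane frame."""
    n = plane.normal
    norm_arm = np.linalg.norm(arm)
    if norm_arm == 0.0:
        raise DegenerateGeometryError("zero-length linker-arm vector")
    a_hat = arm / norm_arm
    sin_beta = np.clip(np.dot(a_hat, n), -1.0, 1.0)
    beta = np.degrees(np.arcsin(sin_beta))
    proj = arm - np.dot(arm, n) * n
    if np.linalg.norm(proj) < 1e-9 * norm_arm:
        return np.nan, beta  # arm ∥ normal: alpha direction undefined
    ref = plane.p3 - 0.5 * (plane.p1 + plane.p2)
    ref = ref - np.dot(ref, n) * n
    nref = np.linalg.norm(ref)
    if nref == 0.0:
        raise DegenerateGeometryError("degenerate in-plane dyad reference")
    alpha = 90.0 - vector_angle(proj, ref / nref)
    return alpha, beta


def compute_linker_angles(
    traj: Trajectory,
    plane_spec: PlaneSpec,
    arm: LinkerArmSpec,
) -> tuple[AngleSeries, AngleSeries]:
    """Per-frame in-plane (α) and out-of-plane (β) linker-arm angles.

    Frames where α is undefined (arm parallel to the normal) carry NaN in
    the α series rather than a fabricated value.
    """
    masses = traj.topology.masses()
    alpha = np.empty(traj.n_frames)
    beta = np.empty(traj.n_frames)
    io = arm.origin_selection.indices
    it = arm.terminal_selection.indices
    for f in range(traj.n_frames):
        xyz = traj.frames[f]
        plane = define_nucleosomal_plane(xyz, plane_spec, masses)
        vec = center_of_mass(xyz[it], masses[it]) - center_of_mass(xyz[io], masses[io])
        alpha[f], beta[f] = _arm_angles(vec, plane)
    return (
        AngleSeries(f"alpha_{arm.side}", alpha),
        AngleSeries(f"beta_{arm.side}", beta),
    )


# ---------------------------------------------------------------------------
# Distances, contacts, RMSD
# ---------------------------------------------------------------------------

def end_to_end_distance(
    traj: Trajectory, sel_a: AtomSelection, sel_b: AtomSelection
) -> np.ndarray:
    """Per-frame Euclidean distance between the two selection COMs, Å."""
    if len(sel_a) == 0 or len(sel_b) == 0:
        raise SelectionEmptyError("end_to_end_distance selections must be non-empty")
    masses = traj.topology.masses()
    ia, ib = sel_a.indices, sel_b.indices
    coms_a = np.array(
        [center_of_mass(traj.frames[f, ia], masses[ia]) for f in range(traj.n_frames)]
    )
    coms_b = np.array(
        [center_of_mass(traj.frames[f, ib], masses[ib]) for f in range(traj.n_frames)]
    )
    return np.linalg.norm(coms_a - coms_b, axis=1)


def contact_table(
    traj: Trajectory,
    sel_a: AtomSelection,
    sel_b: AtomSelection,
    cutoff: float = 4.0,
) -> ContactTable:
    """Residue-pair contacts: any heavy-atom pair within ``cutoff`` Å.

    Hydrogens (element H) are excluded from both selections.  Returns a
    table with per-pair frame counts and fractions plus per-frame total
    contact counts.
    """
    if cutoff <= 0:
        raise ParameterError("contact cutoff must be > 0")
    atoms = traj.topology.atoms
    ia = np.array(
        [i for i in sel_a.indices if atoms[int(i)].element.upper() != "H"], int
    )
    ib = np.array(
        [i for i in sel_b.indices if atoms[int(i)].element.upper() != "H"], int
    )
    if ia.size == 0 or ib.size == 0:
        raise SelectionEmptyError("contact selections contain no heavy atoms")
    res_a = np.array([atoms[int(i)].residue_index for i in ia])
    res_b = np.array([atoms[int(i)].residue_index for i in ib])
    n_frames = traj.n_frames
    pair_masks: dict[tuple[int, int], np.ndarray] = {}
    for f in range(n_frames):
        tree_b = cKDTree(traj.frames[f, ib])
        hits = cKDTree(traj.frames[f, ia]).query_ball_tree(tree_b, cutoff)
        frame_pairs = set()
        for qa, neighbours in enumerate(hits):
            for qb in neighbours:
                frame_pairs.add((int(res_a[qa]), int(res_b[qb])))
        for pair in frame_pairs:
            if pair not in pair_masks:
                pair_masks[pair] = np.zeros(n_frames, dtype=bool)
            pair_masks[pair][f] = True
    rows = [
        {
            "residue_a": ra,
            "residue_b": rb,
            "frames_in_contact": int(mask.sum()),
            "fraction": float(mask.mean()),
            "frame_mask": mask.astype(float),
        }
        for (ra, rb), mask in sorted(pair_masks.items())
    ]
    pairs = pd.DataFrame(
        rows,
        columns=["residue_a", "residue_b", "frames_in_contact", "fraction", "frame_mask"],
    )
    totals = np.zeros(n_frames)
    for mask in pair_masks.values():
        totals += mask
    return ContactTable(pairs=pairs, n_frames=n_frames, per_frame_totals=totals)


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t with R@mobile + t ≈ target."""
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    return rot, tc - rot @ mc


def superpose(
    coords: np.ndarray, fit_idx: np.ndarray, ref_coords: np.ndarray, ref_fit_idx: np.ndarray
) -> np.ndarray:
    rot, trans = kabsch(coords[fit_idx], ref_coords[ref_fit_idx])
    return coords @ rot.T + trans


def rmsd(
    traj: Trajectory,
    fit_sel: AtomSelection,
    measure_sel: AtomSelection,
    reference: StructureFrame,
    ref_fit_sel: AtomSelection | None = None,
    ref_measure_sel: AtomSelection | None = None,
) -> np.ndarray:
    """Per-frame RMSD of ``measure_sel`` after superposing on ``fit_sel``."""
    ref_fit = ref_fit_sel if ref_fit_sel is not None else fit_sel
    ref_measure = ref_measure_sel if ref_measure_sel is not None else measure_sel
    if len(fit_sel) != len(ref_fit) or len(measure_sel) != len(ref_measure):
        raise StructuralMismatchError("fit/measure atom counts differ from reference")
    out = np.empty(traj.n_frames)
    ref_xyz = reference.coords
    for f in range(traj.n_frames):
        aligned = superpose(traj.frames[f], fit_sel.indices, ref_xyz, ref_fit.indices)
        diff = aligned[measure_sel.indices] - ref_xyz[ref_measure.indices]
        out[f] = np.sqrt((diff ** 2).sum(axis=1).mean())
    return out
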