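"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameter record (including the
seed) and returns, alongside its primary artifact, a JSON-serializable
ground-truth record that the test suite consumes.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .core_io import Atom, StructureFrame, Trajectory
from .energetics import COMPONENTS, EnergyTable
from .errors import ConstructionError, ParameterError
from .pre_backcalc import PreParameters, ratio_from_distance
from .wham import KB_KCAL, UmbrellaWindow


def write_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# Toy chromatosome
# ---------------------------------------------------------------------------

@dataclass
class ToyChromatosomeParams:
    n_bp_core: int = 36
    superhelix_radius: float = 42.0
    alpha_entry: float = 0.0
    alpha_exit: float = 0.0
    beta_entry: float = 0.0
    beta_exit: float = 0.0
    lh_pose: str | float = "on_dyad"  # or "off_dyad", or an offset in Å
    coordinate_noise_sd: float = 0.0
    n_frames: int = 1
    seed: int = 0
    arm_length: float = 30.0
    wrap_half_angle: float = 150.0  # degrees of wrap either side of the dyad

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.coordinate_noise_sd < 0:
            raise ParameterError("coordinate_noise_sd must be >= 0")
        if self.superhelix_radius <= 0:
            raise ParameterError("superhelix_radius must be > 0")
        if self.n_bp_core < 8:
            raise ParameterError("n_bp_core must be >= 8")


def _rotate_z(v: np.ndarray, deg: float) -> np.ndarray:
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])


def make_toy_chromatosome(
    params: ToyChromatosomeParams,
) -> tuple[Trajectory, dict]:
    """Pseudo-atom chromatosome with prescribed linker-arm α/β angles.

    The core DNA is a circle of C1'-labeled base pairs in the z = 0 plane
    with the dyad base pair at the top; core-protein pseudo-atoms sit below
    the plane so the analyzed plane normal is +z.  Two straight linker arms
    leave the wrap ends at the prescribed in-plane (α) and out-of-plane (β)
    angles.  Returns the trajectory plus a ground-truth record that includes
    the selection expressions for the plane and both arms.
    """
    for label, val in (
        ("alpha_entry", params.alpha_entry),
        ("alpha_exit", params.alpha_exit),
        ("beta_entry", params.beta_entry),
        ("beta_exit", params.beta_exit),
    ):
        if abs(val) >= 90.0:
            raise ConstructionError(f"{label} = {val}° would fold the arm onto the core")
    n = params.n_bp_core
    radius = params.superhelix_radius
    theta = 90.0 + np.linspace(params.wrap_half_angle, -params.wrap_half_angle, n)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []

    def add(name, element, resid, resname, segid, xyz):
        atoms.append(Atom(name, element, resid, resname, segid))
        coords.append(np.asarray(xyz, float))

    # Core DNA: each base pair contributes two C1' atoms straddling the
    # circle point radially so the pair COM sits exactly on the circle.
    circle_points = []
    for i, th in enumerate(theta, start=1):
        radial = np.array([np.cos(np.radians(th)), np.sin(np.radians(th)), 0.0])
        point = radius * radial
        circle_points.append(point)
        add("C1'", "C", 100 + i, "DA", "DNA", point + 0.5 * radial)
        add("C1'", "C", 500 + i, "DT", "DNA", point - 0.5 * radial)
    circle_points = np.asarray(circle_points)

    # Quadrants along the wrap; the two arcs flanking the dyad are distal
    # from the linker arms (which leave at the wrap ends).
    q = n // 4
    i_dyad = (n + 1) // 2
    quad_a = (i_dyad - q, i_dyad - 1)
    quad_b = (i_dyad + 1, i_dyad + q)

    def bp_expr(lo: int, hi: int) -> str:
        return f"segid DNA and resid {100 + lo}-{100 + hi} {500 + lo}-{500 + hi}"

    # Builder-side plane quantities (all-equal masses; every atom is C1' C).
    def bp_com(lo: int, hi: int) -> np.ndarray:
        return circle_points[lo - 1 : hi].mean(axis=0)

    p1 = bp_com(*quad_a)
    p2 = bp_com(*quad_b)
    p3 = circle_points[i_dyad - 1]
    normal = np.array([0.0, 0.0, 1.0])
    ref = p3 - 0.5 * (p1 + p2)
    ref = ref / np.linalg.norm(ref)

    # Core-protein pseudo-atoms below the plane fix the normal sign to +z.
    rng = np.random.default_rng(params.seed)
    for j in range(16):
        ang = 2 * np.pi * j / 16
        add(
            "CA",
            "C",
            900 + j,
            "ALA",
            "CORE",
            [8.0 * np.cos(ang), 8.0 * np.sin(ang) + radius * 0.1, -5.0],
        )

    def build_arm(side: str, theta_end: float, alpha: float, beta: float, base: int):
        origin = radius * np.array(
            [np.cos(np.radians(theta_end)), np.sin(np.radians(theta_end)), 0.0]
        )
        radial = origin / np.linalg.norm(origin)
        perp = np.cross(normal, ref)  # in-plane, perpendicular to the dyad axis
        baseline = perp if np.dot(perp, radial) > 0 else -perp
        a, b = np.radians(alpha), np.radians(beta)
        direction = np.cos(b) * (np.cos(a) * baseline + np.sin(a) * ref) + np.sin(
            b
        ) * normal
        terminal = origin + params.arm_length * direction
        if np.linalg.norm(terminal[:2]) < 0.5 * radius:
            raise ConstructionError(
                f"{side} arm at alpha={alpha}, beta={beta} intersects the core"
            )
        # Origin/terminal base pairs as C1' atom pairs straddling the point
        # along the plane normal's in-plane perpendicular (COM stays exact).
        offset = 0.5 * np.cross(direction, normal)
        if np.linalg.norm(offset) < 1e-6:
            offset = 0.5 * ref
        for k, (label, point) in enumerate((("origin", origin), ("terminal", terminal))):
            add("C1'", "C", base + 2 * k + 0, "DA", "DNA", point + offset)
            add("C1'", "C", base + 2 * k + 1, "DT", "DNA", point - offset)
        return {
            "origin_expr": f"segid DNA and resid {base}-{base + 1}",
            "terminal_expr": f"segid DNA and resid {base + 2}-{base + 3}",
        }

    theta_entry = 90.0 + params.wrap_half_angle
    theta_exit = 90.0 - params.wrap_half_angle
    entry = build_arm("entry", theta_entry, params.alpha_entry, params.beta_entry, 2001)
    exit_ = build_arm("exit", theta_exit, params.alpha_exit, params.beta_exit, 3001)

    # Linker-histone pseudo-domain: three CA helices + one sheet strand.
    if params.lh_pose == "on_dyad":
        lh_offset = np.array([0.0, 0.0, 0.0])
    elif params.lh_pose == "off_dyad":
        lh_offset = np.array([15.0, -5.0, 0.0])
    else:
        lh_offset = np.array([float(params.lh_pose), 0.0, 0.0])
    lh_center = p3 - 12.0 * ref + np.array([0.0, 0.0, 4.0]) + lh_offset
    resid = 9001
    for h, (dx, dy) in enumerate(((0.0, 0.0), (6.0, 0.0), (0.0, 6.0))):
        for k in range(8):
            add(
                "CA",
                "C",
                resid,
                "ALA",
                "LH",
                lh_center + np.array([dx + 1.5 * k, dy, 2.0 * h]),
            )
            resid += 1
    for k in range(6):
        add("CA", "C", resid, "GLY", "LH", lh_center + np.array([3.0 + 1.5 * k, 9.0, 1.0]))
        resid += 1

    base_coords = np.stack(coords)
    frames = base_coords[None, :, :] + (
        rng.normal(0.0, params.coordinate_noise_sd, size=(params.n_frames,) + base_coords.shape)
        if params.coordinate_noise_sd > 0
        else np.zeros((params.n_frames,) + base_coords.shape)
    )
    topology = StructureFrame(atoms, base_coords)
    traj = Trajectory(topology, frames)

    truth = {
        "params": {k: v for k, v in asdict(params).items()},
        "alpha_entry": params.alpha_entry,
        "alpha_exit": params.alpha_exit,
        "beta_entry": params.beta_entry,
        "beta_exit": params.beta_exit,
        "selections": {
            "quadrant_a": bp_expr(*quad_a),
            "quadrant_b": bp_expr(*quad_b),
            "dyad_pair": bp_expr(i_dyad, i_dyad),
            "core_reference": "segid CORE",
            "entry_origin": entry["origin_expr"],
            "entry_terminal": entry["terminal_expr"],
            "exit_origin": exit_["origin_expr"],
            "exit_terminal": exit_["terminal_expr"],
            "lh": "segid LH",
        },
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Umbrella-window sampling from a known potential
# ---------------------------------------------------------------------------

@dataclass
class SyntheticPotential:
    form: str  # harmonic | double_well | tabulated
    parameters: dict = field(default_factory=dict)
    temperature: float = 300.0

    def energy(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        p = self.parameters
        if self.form == "harmonic":
            return p.get("k", 1.0) * (x - p.get("center", 0.0)) ** 2
        if self.form == "double_well":
            m = 0.5 * (p["min1"] + p["min2"])
            w = 0.5 * abs(p["min2"] - p["min1"])
            return p["barrier"] * ((x - m) ** 2 - w ** 2) ** 2 / w ** 4
        if self.form == "tabulated":
            return np.interp(x, p["x"], p["u"])
        raise ParameterError(f"unknown potential form {self.form!r}")


def sample_umbrella_windows(
    potential: SyntheticPotential,
    centers: np.ndarray,
    force_constant: float,
    n_per_window: int,
    ar1_rho: float = 0.0,
    seed: int = 0,
    half_factor_bias: bool = False,
    domain: tuple[float, float] | None = None,
    grid_points: int = 8001,
) -> tuple[list[UmbrellaWindow], dict]:
    """Correlated samples from the exact biased Boltzmann density.

    Each window's stationary density is ∝ exp(−[U(ξ) + w(ξ)]/kT) with the
    harmonic bias w(ξ) = k(ξ−c)² (optionally with the 1/2 factor).  Samples
    are drawn by inverse-CDF transformation of a Gaussian AR(1) stream
    (coefficient ``ar1_rho``), which gives the exact marginal with lag-1
    autocorrelation ≈ ``ar1_rho``.  The ground-truth PMF (min-shifted) is
    returned alongside.
    """
    centers = np.asarray(centers, float)
    if not -1 < ar1_rho < 1:
        raise ParameterError("ar1_rho must be in (-1, 1)")
    kt = KB_KCAL * potential.temperature
    if domain is None:
        pad = 6.0 * np.sqrt(kt / max(force_constant, 1e-6))
        domain = (centers.min() - pad, centers.max() + pad)
    grid = np.linspace(domain[0], domain[1], grid_points)
    u_grid = potential.energy(grid)
    rng = np.random.default_rng(seed)
    windows = []
    factor = 0.5 if half_factor_bias else 1.0
    for c in centers:
        bias = factor * force_constant * (grid - c) ** 2
        logw = -(u_grid + bias) / kt
        logw -= logw.max()
        dens = np.exp(logw)
        cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]))])
        cdf /= cdf[-1]
        # Gaussian AR(1) -> uniform via Phi -> target marginal via CDF^-1
        eps = rng.standard_normal(n_per_window)
        z = np.empty(n_per_window)
        z[0] = eps[0]
        scale = np.sqrt(1.0 - ar1_rho ** 2)
        for t in range(1, n_per_window):
            z[t] = ar1_rho * z[t - 1] + scale * eps[t]
        u = ndtr(z)
        # strictly increasing CDF for interpolation: drop flat tails
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        samples = np.interp(u, cdf[keep], grid[keep])
        windows.append(UmbrellaWindow(float(c), force_constant, samples))
    pmf = u_grid - u_grid.min()
    truth = {
        "grid": grid,
        "pmf": pmf,
        "temperature": potential.temperature,
        "force_constant": force_constant,
        "centers": centers,
        "ar1_rho": ar1_rho,
        "seed": seed,
    }
    return windows, truth


# ---------------------------------------------------------------------------
# PRE dataset
# ---------------------------------------------------------------------------

def make_pre_dataset(
    true_distances: pd.DataFrame | dict[int, float],
    params: PreParameters | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 1,
    ensemble_jitter_sd: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Noisy 'experimental' ratios plus a per-frame ensemble distance table.

    ``true_distances``: residue -> probe distance (Å).  Experimental ratios
    are the exact model ratios with clipped Gaussian noise; the ensemble has
    each distance jittered per frame (both methyls share the truth).
    """
    params = params or PreParameters()
    if isinstance(true_distances, dict):
        true_distances = pd.DataFrame(
            {"residue": list(true_distances), "r": list(true_distances.values())}
        )
    if (true_distances["r"] <= 0).any():
        raise ParameterError("true distances must be > 0")
    rng = np.random.default_rng(seed)
    r_true = true_distances["r"].to_numpy(float)
    ratios = ratio_from_distance(r_true, params)
    noisy = np.clip(ratios + rng.normal(0.0, noise_sd, size=ratios.shape), 0.0, 1.0)
    experimental = pd.DataFrame(
        {
            "residue_index": true_distances["residue"].astype(int),
            "ratio": noisy,
            "error": np.full(ratios.shape, noise_sd),
        }
    )
    rows = []
    for f in range(n_frames):
        jitter_a = rng.normal(0.0, ensemble_jitter_sd, size=r_true.shape)
        jitter_b = rng.normal(0.0, ensemble_jitter_sd, size=r_true.shape)
        for res, r, ja, jb in zip(true_distances["residue"], r_true, jitter_a, jitter_b):
            rows.append(
                {
                    "frame": f,
                    "residue": int(res),
                    "r_methyl_a": max(float(r + ja), 0.0),
                    "r_methyl_b": max(float(r + jb), 0.0),
                }
            )
    ensemble = pd.DataFrame(rows)
    truth = {
        "true_distances": dict(
            zip(true_distances["residue"].astype(int), r_true)
        ),
        "true_ratios": dict(zip(true_distances["residue"].astype(int), ratios)),
        "noise_sd": noise_sd,
        "ensemble_jitter_sd": ensemble_jitter_sd,
        "n_frames": n_frames,
        "seed": seed,
    }
    return ensemble, experimental, truth


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

def make_energy_tables(
    component_means: dict[str, dict[str, float]],
    sds: dict[str, dict[str, float]] | float = 0.0,
    n_frames: int = 100,
    seed: int = 0,
) -> tuple[dict[str, EnergyTable], dict]:
    """Independent Gaussian per-frame component tables per role.

    ``component_means``: role -> {E_internal, E_elec, E_vdw} means.  ``sds``
    mirrors the structure or is a scalar applied everywhere.  Totals are row
    sums of the components.
    """
    rng = np.random.default_rng(seed)
    tables = {}
    for role, means in component_means.items():
        data = {}
        for comp in COMPONENTS:
            if comp not in means:
                raise ParameterError(f"role {role!r} missing component {comp!r}")
            sd = sds if np.isscalar(sds) else sds.get(role, {}).get(comp, 0.0)
            if sd < 0:
                raise ParameterError("sds must be >= 0")
            data[comp] = means[comp] + rng.normal(0.0, sd, size=n_frames)
        df = pd.DataFrame(data)
        df["E_total"] = df[list(COMPONENTS)].sum(axis=1)
        tables[role] = EnergyTable(role=role, frames=df)
    truth = {
        "component_means": component_means,
        "implied_totals": {
            role: float(sum(m[c] for c in COMPONENTS))
            for role, m in component_means.items()
        },
        "n_frames": n_frames,
        "seed": seed,
    }
    return tables, truth


# ---------------------------------------------------------------------------
# Two-state trajectory for clustering
# ---------------------------------------------------------------------------

def make_two_state_trajectory(
    n_frames: int = 100,
    state_fractions: tuple[float, float] = (0.5, 0.5),
    inter_state_rmsd: float = 5.0,
    intra_state_sd: float = 0.3,
    seed: int = 0,
    n_core: int = 30,
    n_mobile: int = 20,
) -> tuple[Trajectory, np.ndarray, dict]:
    """CA pseudo-structures around two conformers of a mobile domain.

    The core atoms are identical between states (superposition anchor); the
    mobile atoms of state 1 are displaced so the measure-selection RMSD to
    state 0 is exactly ``inter_state_rmsd`` at zero noise.  Returns the
    trajectory, per-frame true state labels, and a ground-truth record with
    the fit/measure selection expressions.
    """
    if abs(sum(state_fractions) - 1.0) > 1e-9:
        raise ParameterError("state_fractions must sum to 1")
    rng = np.random.default_rng(seed)
    core = np.column_stack(
        [np.linspace(0, 3.8 * (n_core - 1), n_core), np.zeros(n_core), np.zeros(n_core)]
    )
    core += rng.normal(0, 2.0, core.shape)  # give the anchor some shape
    mobile = np.column_stack(
        [
            np.linspace(0, 3.8 * (n_mobile - 1), n_mobile),
            np.full(n_mobile, 10.0),
            np.full(n_mobile, 5.0),
        ]
    )
    mobile += rng.normal(0, 2.0, mobile.shape)
    disp = rng.standard_normal((n_mobile, 3))
    disp *= inter_state_rmsd / np.sqrt((disp ** 2).sum(axis=1).mean())
    n1 = int(round(state_fractions[1] * n_frames))
    labels = np.zeros(n_frames, dtype=int)
    labels[rng.permutation(n_frames)[:n1]] = 1
    atoms = [Atom("CA", "C", i + 1, "ALA", "CORE") for i in range(n_core)] + [
        Atom("CA", "C", 100 + i + 1, "ALA", "LH") for i in range(n_mobile)
    ]
    base = np.vstack([core, mobile])
    frames = np.empty((n_frames, base.shape[0], 3))
    for f in range(n_frames):
        xyz = base.copy()
        if labels[f] == 1:
            xyz[n_core:] += disp
        if intra_state_sd > 0:
            xyz += rng.normal(0.0, intra_state_sd, xyz.shape)
        frames[f] = xyz
    traj = Trajectory(StructureFrame(atoms, base), frames)
    truth = {
        "labels": labels,
        "state_fractions": list(state_fractions),
        "inter_state_rmsd": inter_state_rmsd,
        "intra_state_sd": intra_state_sd,
        "seed": seed,
        "selections": {"fit": "segid CORE and name CA", "measure": "segid LH and name CA"},
    }
    return traj, labels, truth
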