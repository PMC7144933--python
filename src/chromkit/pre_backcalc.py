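"""Back-calculation of PRE cross-peak intensity ratios from distances.

The condensed ratio model is

    I_ox / I_red = exp(-beta * (r + d)^-6) / (1 + alpha * (r + d)^-6)

with alpha = 4.5e8, beta = 3.4e7 and d = 9.0 Å.  NOTE: the source
formulation is sometimes printed with a positive exponent; that form
diverges as r -> 0 and contradicts the underlying relaxation model, where
the paramagnetic rate attenuates intensity.  The negative exponent used
here gives the physical limits ratio -> 1 far from the probe and -> 0 near
it.

A physical-parameter mode evaluates the uncondensed two-equation model
(intrinsic rate R2, probe contribution R2sp derived from an r^-6 law) and
can regenerate condensed constants for consistency checking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .core_io import StructureFrame, Trajectory
from .errors import NoOverlapError, ParameterError, ProbeResolutionError

# Terminal methyl carbons of standard residues (PDB atom names).
METHYL_CARBONS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "VAL": ("CG1", "CG2"),
    "LEU": ("CD1", "CD2"),
    "ILE": ("CG2", "CD1"),
    "THR": ("CG2",),
    "MET": ("CE",),
}

# Probe-atom rules: residue name -> atom used as the label proxy.
PROBE_ATOM_RULES: dict[str, str] = {
    "LYS": "NZ",  # lysine terminal nitrogen
    "THR": "CG2",  # threonine terminal methyl carbon
}


@dataclass
class PreParameters:
    alpha_const: float = 4.5e8
    beta_const: float = 3.4e7
    d_offset: float = 9.0  # Å
    physical: dict | None = None  # optional {K, tau_c, omega_h, R2, t_evol}

    def __post_init__(self) -> None:
        if self.alpha_const <= 0 or self.beta_const <= 0:
            raise ParameterError("alpha_const and beta_const must be > 0")
        if self.d_offset < 0:
            raise ParameterError("d_offset must be >= 0")


@dataclass
class ProbeSpec:
    probe_residue: int
    probe_segment: str | None = None
    probe_atom_rule: str | None = None  # explicit atom name; default by resname


@dataclass
class PreProfile:
    table: pd.DataFrame  # residue_index, ratio_methyl_a, ratio_methyl_b,
    #                       ratio_mean, ci80_low, ci80_high
    source: str = "ensemble"
    params: PreParameters = field(default_factory=PreParameters)


# ---------------------------------------------------------------------------
# Ratio model
# ---------------------------------------------------------------------------

def ratio_from_distance(r, params: PreParameters | None = None):
    """Intensity ratio for probe-methyl distance(s) r (Å); in (0, 1]."""
    params = params or PreParameters()
    r = np.asarray(r, float)
    if np.any(r < 0):
        raise ParameterError("distances must be >= 0")
    x = (r + params.d_offset) ** -6
    ratio = np.exp(-params.beta_const * x) / (1.0 + params.alpha_const * x)
    out = np.clip(ratio, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def distance_from_ratio(
    ratio: float, params: PreParameters | None = None, bracket=(0.0, 1e4)
) -> float:
    """Numerical inverse of :func:`ratio_from_distance` (bisection)."""
    params = params or PreParameters()
    if not 0 < ratio < 1:
        raise ParameterError("ratio must be in (0, 1) for inversion")
    lo, hi = bracket
    f = lambda r: ratio_from_distance(r, params) - ratio
    if f(lo) > 0 or f(hi) < 0:
        raise ParameterError("ratio outside the invertible range of the model")
    return float(brentq(f, lo, hi, xtol=1e-9))


def ratio_physical(r, physical: dict):
    """Uncondensed two-equation model.

    ``physical`` requires K (cm^6 s^-2), tau_c (s), omega_h (rad/s),
    R2 (s^-1) and t_evol (s).  Distances r in Å.
    """
    required = {"K", "tau_c", "omega_h", "R2", "t_evol"}
    missing = required - set(physical)
    if missing:
        raise ParameterError(f"physical parameter set missing {sorted(missing)}")
    r_cm = np.asarray(r, float) * 1e-8  # Å -> cm
    tau = physical["tau_c"]
    spectral = 4.0 * tau + 3.0 * tau / (1.0 + physical["omega_h"] ** 2 * tau ** 2)
    r2sp = physical["K"] * spectral / r_cm ** 6
    r2 = physical["R2"]
    out = r2 * np.exp(-r2sp * physical["t_evol"]) / (r2 + r2sp)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def condense_physical(physical: dict) -> PreParameters:
    """Regenerate condensed (alpha, beta) constants from physical inputs.

    With R2sp = K * S(tau_c) * r^-6 the exact ratio is
    exp(-R2sp t) / (1 + R2sp / R2), i.e. alpha = K S / R2 and
    beta = K S t_evol in Å^6 units, with no distance offset.
    """
    tau = physical["tau_c"]
    spectral = 4.0 * tau + 3.0 * tau / (1.0 + physical["omega_h"] ** 2 * tau ** 2)
    ks = physical["K"] * spectral * (1e8) ** 6  # cm^6 -> Å^6
    return PreParameters(
        alpha_const=ks / physical["R2"],
        beta_const=ks * physical["t_evol"],
        d_offset=0.0,
    )


# ---------------------------------------------------------------------------
# Structure-based distances
# ---------------------------------------------------------------------------

def _resolve_probe_atom(frame: StructureFrame, probe: ProbeSpec) -> int:
    hits = []
    for i, a in enumerate(frame.atoms):
        if a.residue_index != probe.probe_residue:
            continue
        if probe.probe_segment is not None and a.segment_id != probe.probe_segment:
            continue
        rule = probe.probe_atom_rule or PROBE_ATOM_RULES.get(a.residue_name)
        if rule is None:
            raise ProbeResolutionError(
                f"no probe-atom rule for residue {a.residue_name} "
                f"{probe.probe_residue}; set probe_atom_rule"
            )
        if a.name == rule:
            hits.append(i)
    if len(hits) != 1:
        raise ProbeResolutionError(
            f"probe rule resolved to {len(hits)} atoms for residue "
            f"{probe.probe_residue} (need exactly 1)"
        )
    return hits[0]


def probe_methyl_distances(
    frame: StructureFrame,
    probe: ProbeSpec,
    targets: list[int],
    target_segment: str | None = None,
) -> pd.DataFrame:
    """Distances from the probe atom to each target residue's methyl carbons.

    Rows: residue, r_methyl_a, r_methyl_b, single_methyl (flag; for residues
    with one methyl r_methyl_b duplicates r_methyl_a).
    """
    probe_idx = _resolve_probe_atom(frame, probe)
    probe_xyz = frame.coords[probe_idx]
    rows = []
    for res in targets:
        methyl_idx = []
        resname = None
        for i, a in enumerate(frame.atoms):
            if a.residue_index != res:
                continue
            if target_segment is not None and a.segment_id != target_segment:
                continue
            resname = a.residue_name
            names = METHYL_CARBONS.get(a.residue_name, ())
            if a.name in names:
                methyl_idx.append(i)
        if not methyl_idx:
            raise ProbeResolutionError(
                f"target residue {res} ({resname}) has no recognizable methyl carbon"
            )
        d = np.linalg.norm(frame.coords[methyl_idx] - probe_xyz, axis=1)
        single = len(methyl_idx) == 1
        rows.append(
            {
                "residue": res,
                "r_methyl_a": float(d[0]),
                "r_methyl_b": float(d[1] if not single else d[0]),
                "single_methyl": single,
            }
        )
    return pd.DataFrame(rows)


def predict_profile(
    ensemble: Trajectory,
    probe: ProbeSpec,
    targets: list[int],
    params: PreParameters | None = None,
    target_segment: str | None = None,
) -> PreProfile:
    """Time-averaged per-residue intensity ratios with 80% percentile CI.

    Per frame, each methyl distance is converted to a ratio and methyl-a/b
    are averaged; the per-residue ratio is the time average of those
    per-frame means, with the CI taken from their empirical 10th/90th
    percentiles (collapsed for a single frame).
    """
    params = params or PreParameters()
    if ensemble.n_frames < 1:
        raise ParameterError("ensemble must contain at least one frame")
    per_frame: dict[int, list[tuple[float, float]]] = {t: [] for t in targets}
    for f in range(ensemble.n_frames):
        frame = ensemble.frame(f)
        table = probe_methyl_distances(frame, probe, targets, target_segment)
        for _, row in table.iterrows():
            ra = ratio_from_distance(row["r_methyl_a"], params)
            rb = ratio_from_distance(row["r_methyl_b"], params)
            per_frame[int(row["residue"])].append((ra, rb))
    rows = []
    for res in targets:
        pairs = np.array(per_frame[res])
        frame_means = pairs.mean(axis=1)
        lo, hi = (
            (frame_means[0], frame_means[0])
            if frame_means.size == 1
            else np.percentile(frame_means, [10, 90])
        )
        rows.append(
            {
                "residue_index": res,
                "ratio_methyl_a": float(pairs[:, 0].mean()),
                "ratio_methyl_b": float(pairs[:, 1].mean()),
                "ratio_mean": float(frame_means.mean()),
                "ci80_low": float(lo),
                "ci80_high": float(hi),
            }
        )
    source = "single-structure" if ensemble.n_frames == 1 else "ensemble"
    return PreProfile(pd.DataFrame(rows), source=source, params=params)


def profile_from_distances(
    distances: pd.DataFrame, params: PreParameters | None = None
) -> PreProfile:
    """Profile from a per-frame distance table (columns: frame, residue,
    r_methyl_a, r_methyl_b) — the ensemble path without coordinates."""
    params = params or PreParameters()
    rows = []
    for res, grp in distances.groupby("residue"):
        ra = ratio_from_distance(grp["r_methyl_a"].to_numpy(), params)
        rb = ratio_from_distance(grp["r_methyl_b"].to_numpy(), params)
        frame_means = 0.5 * (ra + rb)
        lo, hi = (
            (frame_means[0], frame_means[0])
            if frame_means.size == 1
            else np.percentile(frame_means, [10, 90])
        )
        rows.append(
            {
                "residue_index": int(res),
                "ratio_methyl_a": float(np.mean(ra)),
                "ratio_methyl_b": float(np.mean(rb)),
                "ratio_mean": float(frame_means.mean()),
                "ci80_low": float(lo),
                "ci80_high": float(hi),
            }
        )
    n_frames = distances["frame"].nunique() if "frame" in distances else 1
    return PreProfile(
        pd.DataFrame(rows).sort_values("residue_index").reset_index(drop=True),
        source="single-structure" if n_frames == 1 else "ensemble",
        params=params,
    )


# ---------------------------------------------------------------------------
# Comparison to experiment
# ---------------------------------------------------------------------------

@dataclass
class PreComparison:
    mean_signed_error: float
    mean_absolute_error: float
    residuals: pd.DataFrame  # residue_index, predicted, experimental, residual
    fraction_within_ci: float
    only_predicted: list[int]
    only_experimental: list[int]


def compare_to_experiment(
    predicted: PreProfile, experimental: pd.DataFrame
) -> PreComparison:
    """Signed residuals (predicted − experimental) over shared residues.

    ``experimental`` needs columns residue_index (or residue) and ratio.
    """
    exp = experimental.rename(columns={"residue": "residue_index"})
    if "residue_index" not in exp.columns or "ratio" not in exp.columns:
        raise ParameterError("experimental table needs residue_index and ratio columns")
    pred = predicted.table
    merged = pred.merge(exp, on="residue_index", how="inner", suffixes=("", "_exp"))
    if merged.empty:
        raise NoOverlapError("no residues shared between predicted and experimental")
    merged["residual"] = merged["ratio_mean"] - merged["ratio"]
    within = (merged["ratio"] >= merged["ci80_low"]) & (
        merged["ratio"] <= merged["ci80_high"]
    )
    residuals = merged[
        ["residue_index", "ratio_mean", "ratio", "residual"]
    ].rename(columns={"ratio_mean": "predicted", "ratio": "experimental"})
    return PreComparison(
        mean_signed_error=float(merged["residual"].mean()),
        mean_absolute_error=float(merged["residual"].abs().mean()),
        residuals=residuals,
        fraction_within_ci=float(within.mean()),
        only_predicted=sorted(
            set(pred["residue_index"]) - set(exp["residue_index"])
        ),
        only_experimental=sorted(
            set(exp["residue_index"]) - set(pred["residue_index"])
        ),
    )
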