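"""Structure/trajectory I/O, atom selection, configuration and logging.

The portable trajectory dialects are multi-model PDB and a plain
``frame-table`` CSV (columns ``frame, atom_index, x, y, z``).  Residue
numbering is always the source file's 1-based numbering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    EmptyStructureError,
    ParameterError,
    PDBParseError,
    SelectionSyntaxError,
    StructuralMismatchError,
)

logger = logging.getLogger("chromkit")

# Standard atomic masses for COM weighting; anything else gets unit mass.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "MG": 24.305,
    "NA": 22.990,
    "CL": 35.45,
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_index: int
    residue_name: str
    segment_id: str


@dataclass
class StructureFrame:
    """A labeled set of atoms with one coordinate per atom (Å)."""

    atoms: list[Atom]
    coords: np.ndarray  # (n_atoms, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise StructuralMismatchError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.atoms)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ParameterError("non-finite coordinates in structure")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def masses(self) -> np.ndarray:
        """Per-atom masses; unit mass for unknown elements."""
        return np.array(
            [ATOMIC_MASSES.get(a.element.upper(), 1.0) for a in self.atoms]
        )

    def with_coords(self, coords: np.ndarray) -> "StructureFrame":
        return StructureFrame(self.atoms, np.asarray(coords, dtype=float))


@dataclass
class Trajectory:
    """An ordered stack of frames sharing one topology."""

    topology: StructureFrame
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise StructuralMismatchError(
                f"frames must be (n_frames, n_atoms, 3), got {self.frames.shape}"
            )
        if self.frames.shape[1] != self.topology.n_atoms:
            raise StructuralMismatchError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame(self, i: int) -> StructureFrame:
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class AtomSelection:
    expression: str
    resolved_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.resolved_indices, dtype=int)
        object.__setattr__(self, "resolved_indices", idx)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ParameterError("resolved_indices must be strictly increasing")

    @property
    def indices(self) -> np.ndarray:
        return self.resolved_indices

    def __len__(self) -> int:
        return int(self.resolved_indices.size)


@dataclass
class AnalysisConfig:
    """Run configuration shared by the CLI subcommands."""

    selections: dict[str, str] = field(default_factory=dict)
    equilibration_cut: int = 0
    histogram_bins: int = 50
    seed: int = 0
    contact_cutoff: float = 4.0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.equilibration_cut < 0:
            raise ParameterError("equilibration_cut must be >= 0")
        if self.histogram_bins < 2:
            raise ParameterError("histogram_bins must be >= 2")
        if self.contact_cutoff <= 0:
            raise ParameterError("contact_cutoff must be > 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {
            k: raw[k]
            for k in (
                "selections",
                "equilibration_cut",
                "histogram_bins",
                "seed",
                "contact_cutoff",
            )
            if k in raw
        }
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(extra=extra, **known)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "selections": self.selections,
                "equilibration_cut": self.equilibration_cut,
                "histogram_bins": self.histogram_bins,
                "seed": self.seed,
                "contact_cutoff": self.contact_cutoff,
                "extra": self.extra,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _parse_atom_record(line: str, lineno: int) -> tuple[Atom, tuple[float, float, float]]:
    if len(line) < 54:
        raise PDBParseError("ATOM/HETATM record shorter than 54 columns", lineno)
    try:
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed ATOM/HETATM fields ({exc})", lineno) from exc
    segid = line[72:76].strip() if len(line) >= 76 else ""
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # PDB v3 fallback: first alphabetic character of the atom name.
        m = re.search(r"[A-Za-z]", name)
        element = m.group(0).upper() if m else ""
    return Atom(name, element, resseq, resname, segid or chain), (x, y, z)


def _read_pdb_models(path: str | Path) -> list[tuple[list[Atom], np.ndarray]]:
    models: list[tuple[list[Atom], np.ndarray]] = []
    atoms: list[Atom] = []
    xyz: list[tuple[float, float, float]] = []
    in_model = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model = True
                if atoms:
                    models.append((atoms, np.array(xyz)))
                    atoms, xyz = [], []
            elif rec == "ENDMDL":
                in_model = False
                if atoms:
                    models.append((atoms, np.array(xyz)))
                    atoms, xyz = [], []
            elif rec in ("ATOM", "HETATM"):
                atom, coord = _parse_atom_record(line.rstrip("\n"), lineno)
                atoms.append(atom)
                xyz.append(coord)
            elif rec in ("TER", "END", "REMARK", "TITLE", "CRYST1", ""):
                continue
    if atoms:
        models.append((atoms, np.array(xyz)))
    return models


def read_structure(path: str | Path, dialect: str = "pdb") -> StructureFrame:
    """Read a single structure (first model of a PDB file)."""
    if dialect != "pdb":
        raise ParameterError(f"unknown structure dialect {dialect!r}")
    models = _read_pdb_models(path)
    if not models:
        raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
    if len(models) > 1:
        logger.warning(
            "%s contains %d models; reading the first only", path, len(models)
        )
    atoms, xyz = models[0]
    return StructureFrame(atoms, xyz)


def read_trajectory(
    path: str | Path,
    dialect: str = "multi-model-pdb",
    topology: StructureFrame | None = None,
) -> Trajectory:
    """Read a trajectory; frames are ordered as in the file.

    The ``frame-table`` dialect has no atom metadata, so a placeholder (or
    user-supplied) topology is attached.
    """
    if dialect == "multi-model-pdb":
        models = _read_pdb_models(path)
        if not models:
            raise EmptyStructureError(f"{path}: no ATOM/HETATM records")
        top_atoms, first = models[0]
        frames = [first]
        for i, (atoms, xyz) in enumerate(models[1:], start=2):
            if len(atoms) != len(top_atoms):
                raise StructuralMismatchError(
                    f"frame {i} has {len(atoms)} atoms, frame 1 has {len(top_atoms)}"
                )
            frames.append(xyz)
        return Trajectory(StructureFrame(top_atoms, first), np.stack(frames))
    if dialect == "frame-table":
        df = pd.read_csv(path)
        required = {"frame", "atom_index", "x", "y", "z"}
        missing = required - set(df.columns)
        if missing:
            raise PDBParseError(f"frame-table missing columns {sorted(missing)}")
        df = df.sort_values(["frame", "atom_index"], kind="mergesort")
        counts = df.groupby("frame").size()
        if counts.nunique() > 1:
            bad = counts[counts != counts.iloc[0]].index[0]
            raise StructuralMismatchError(
                f"frame {bad} has {counts[bad]} atoms, expected {counts.iloc[0]}"
            )
        n_atoms = int(counts.iloc[0])
        frames = df[["x", "y", "z"]].to_numpy(float).reshape(-1, n_atoms, 3)
        if topology is None:
            topology = StructureFrame(
                [Atom("X", "", i + 1, "UNK", "A") for i in range(n_atoms)],
                frames[0],
            )
        return Trajectory(topology, frames)
    raise ParameterError(f"unknown trajectory dialect {dialect!r}")


def _format_atom_line(i: int, atom: Atom, xyz: np.ndarray) -> str:
    name = atom.name if len(atom.name) >= 4 else f" {atom.name:<3s}"
    return (
        f"ATOM  {min(i, 99999):5d} {name:<4.4s} {atom.residue_name:<3.3s} "
        f"{'A':1s}{atom.residue_index % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}      "
        f"{atom.segment_id:<4.4s}{atom.element:>2.2s}"
    )


def write_structure(frame: StructureFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, (atom, xyz) in enumerate(zip(frame.atoms, frame.coords), start=1):
            fh.write(_format_atom_line(i, atom, xyz) + "\n")
        fh.write("END\n")


def write_trajectory(
    traj: Trajectory, path: str | Path, dialect: str = "multi-model-pdb"
) -> None:
    if dialect == "multi-model-pdb":
        with open(path, "w") as fh:
            for m in range(traj.n_frames):
                fh.write(f"MODEL     {m + 1:4d}\n")
                for i, atom in enumerate(traj.topology.atoms):
                    fh.write(_format_atom_line(i + 1, atom, traj.frames[m, i]) + "\n")
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    if dialect == "frame-table":
        n_frames, n_atoms = traj.n_frames, traj.n_atoms
        df = pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_frames), n_atoms),
                "atom_index": np.tile(np.arange(n_atoms), n_frames),
                "x": traj.frames[:, :, 0].ravel(),
                "y": traj.frames[:, :, 1].ravel(),
                "z": traj.frames[:, :, 2].ravel(),
            }
        )
        df.to_csv(path, index=False, float_format="%.9f")
        return
    raise ParameterError(f"unknown trajectory dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Atom selection
# ---------------------------------------------------------------------------

_KEYWORDS = ("name", "resid", "resname", "segid", "element")


def _clause_mask(topology: StructureFrame, clause: str, offset: int) -> np.ndarray:
    tokens = clause.split()
    if not tokens:
        raise SelectionSyntaxError("empty clause", offset)
    keyword, values = tokens[0], tokens[1:]
    if keyword not in _KEYWORDS:
        raise SelectionSyntaxError(
            f"unknown keyword {keyword!r} (expected one of {_KEYWORDS})", offset
        )
    if not values:
        raise SelectionSyntaxError(f"keyword {keyword!r} needs values", offset)
    atoms = topology.atoms
    if keyword == "resid":
        mask = np.zeros(len(atoms), dtype=bool)
        resids = np.array([a.residue_index for a in atoms])
        for v in values:
            m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", v)
            if not m:
                raise SelectionSyntaxError(f"bad resid token {v!r}", offset)
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            mask |= (resids >= lo) & (resids <= hi)
        return mask
    getter = {
        "name": lambda a: a.name,
        "resname": lambda a: a.residue_name,
        "segid": lambda a: a.segment_id,
        "element": lambda a: a.element.upper(),
    }[keyword]
    wanted = {v.upper() if keyword == "element" else v for v in values}
    return np.array([getter(a) in wanted for a in atoms])


def resolve_selection(topology: StructureFrame, expression: str) -> AtomSelection:
    """Resolve a selection expression against a topology.

    Grammar: clauses of ``keyword value [value ...]`` joined with ``and``;
    keywords are ``name``, ``resid`` (ranges ``lo-hi``), ``resname``,
    ``segid`` and ``element``.
    """
    if not expression.strip():
        raise SelectionSyntaxError("empty expression", 0)
    mask = np.ones(topology.n_atoms, dtype=bool)
    offset = 0
    for part in re.split(r"\band\b", expression):
        mask &= _clause_mask(topology, part.strip(), offset)
        offset += len(part) + 3
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        logger.warning("selection %r matched no atoms", expression)
    return AtomSelection(expression, indices)


def heavy_atom_subset(topology: StructureFrame, selection: AtomSelection) -> AtomSelection:
    """Drop hydrogens (by element) from a selection."""
    keep = [
        i
        for i in selection.indices
        if topology.atoms[int(i)].element.upper() != "H"
    ]
    return AtomSelection(selection.expression + " and not element H", np.array(keep, int))


# ---------------------------------------------------------------------------
# Logging / provenance
# ---------------------------------------------------------------------------

def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def provenance_header(config: AnalysisConfig | None, seed: int | None) -> dict:
    """Machine-readable run header echoed at the top of every CLI run."""
    return {
        "tool": "chromkit",
        "config_hash": config.config_hash() if config is not None else None,
        "seed": seed,
    }


def log_provenance(config: AnalysisConfig | None, seed: int | None) -> None:
    logger.info("run %s", json.dumps(provenance_header(config, seed)))
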