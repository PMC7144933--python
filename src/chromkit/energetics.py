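"""Three-trajectory MM/GBSA assembly and strain decomposition.

Per-frame energy component tables (internal, electrostatic, van der Waals,
total) are ingested per role (complex / receptor / ligand); binding energies
are differences of per-role means with uncertainties combined in quadrature
(the three trajectories are independent).  The ± values are per-frame
standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError

logger = logging.getLogger("chromkit.energetics")

COMPONENTS = ("E_internal", "E_elec", "E_vdw")
ALL_COLUMNS = COMPONENTS + ("E_total",)
ROLES = ("complex", "receptor", "ligand")


@dataclass
class EnergyTable:
    role: str
    frames: pd.DataFrame  # columns ALL_COLUMNS, one row per frame

    def __post_init__(self) -> None:
        if self.role not in ROLES + ("nuc", "lh", "species"):
            raise ParameterError(f"unknown role {self.role!r}")
        missing = set(ALL_COLUMNS) - set(self.frames.columns)
        if missing:
            raise SchemaError(f"energy table missing columns {sorted(missing)}")
        resid = (
            self.frames["E_total"]
            - self.frames[list(COMPONENTS)].sum(axis=1)
        ).abs()
        if (resid > 1e-6).any():
            logger.warning(
                "%s: E_total inconsistent by up to %.3g; recomputing totals",
                self.role,
                float(resid.max()),
            )
            self.frames = self.frames.copy()
            self.frames["E_total"] = self.frames[list(COMPONENTS)].sum(axis=1)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def means(self) -> pd.Series:
        return self.frames[list(ALL_COLUMNS)].mean()

    def sds(self) -> pd.Series:
        return self.frames[list(ALL_COLUMNS)].std(ddof=1)


@dataclass
class BindingSummary:
    """Per-component ΔE = mean(complex) − mean(receptor) − mean(ligand)."""

    mean: pd.Series  # index ALL_COLUMNS
    sd: pd.Series
    n_frames: dict[str, int]

    @classmethod
    def from_values(
        cls, means: dict[str, float], sds: dict[str, float] | None = None
    ) -> "BindingSummary":
        """Build a summary from already-assembled ΔE values (e.g. published
        tables) so they can be fed to delta_delta."""
        mean = pd.Series({c: means.get(c, np.nan) for c in ALL_COLUMNS})
        sd = pd.Series({c: (sds or {}).get(c, 0.0) for c in ALL_COLUMNS})
        return cls(mean=mean, sd=sd, n_frames={})

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


@dataclass
class StrainSummary:
    """Per-component strain ΔΔE = mean(complexed) − mean(isolated).

    Negative values mean the complexed ensemble is lower in energy.
    """

    species: str
    mean: pd.Series
    sd: pd.Series

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})


def read_energy_table(path: str | Path, role: str) -> EnergyTable:
    """Read a per-frame component CSV; totals validated (recomputed with a
    warning on mismatch)."""
    df = pd.read_csv(path)
    missing = set(ALL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    bad = df[list(ALL_COLUMNS)].isna().any(axis=1)
    if bad.any():
        raise SchemaError(f"{path}: non-numeric rows at index {list(df.index[bad])[:5]}")
    return EnergyTable(role=role, frames=df[list(ALL_COLUMNS)].astype(float))


def write_energy_table(table: EnergyTable, path: str | Path) -> None:
    table.frames.to_csv(path, index=False)


def gbsa_binding(
    complex_table: EnergyTable,
    receptor: EnergyTable,
    ligand: EnergyTable,
) -> BindingSummary:
    """Three-trajectory binding energy per component, SD in quadrature."""
    got = {complex_table.role, receptor.role, ligand.role}
    if got != set(ROLES):
        raise ParameterError(f"need roles {ROLES}, got {sorted(got)}")
    by_role = {t.role: t for t in (complex_table, receptor, ligand)}
    mean = (
        by_role["complex"].means()
        - by_role["receptor"].means()
        - by_role["ligand"].means()
    )
    sd = np.sqrt(
        by_role["complex"].sds() ** 2
        + by_role["receptor"].sds() ** 2
        + by_role["ligand"].sds() ** 2
    ).fillna(0.0)
    return BindingSummary(
        mean=mean,
        sd=sd,
        n_frames={r: by_role[r].n_frames for r in ROLES},
    )


def delta_delta(on: BindingSummary, off: BindingSummary) -> BindingSummary:
    """ΔΔE between binding modes (on − off); negative favors ``on``."""
    return BindingSummary(
        mean=on.mean - off.mean,
        sd=np.sqrt(on.sd ** 2 + off.sd ** 2),
        n_frames={"on": on.n_frames, "off": off.n_frames},
    )


def strain(
    species_complexed: EnergyTable, species_isolated: EnergyTable, species: str = "species"
) -> StrainSummary:
    """Energetic strain of one species between its complexed and isolated
    ensembles, per component."""
    return StrainSummary(
        species=species,
        mean=species_complexed.means() - species_isolated.means(),
        sd=np.sqrt(species_complexed.sds() ** 2 + species_isolated.sds() ** 2).fillna(0.0),
    )
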