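"""Chain-conformation metrics: radius of gyration, end-to-end distance,
characteristic viscosity.

The radius of gyration R_g — the mass-weighted RMS distance of atoms from
their center of mass — measures chain compactness: a spread, well-hydrated
chain has a large R_g, a collapsed globule a small one.  The characteristic
viscosity η of a dilute polymer solution scales with the pervaded volume
per unit mass, η ∝ R_g³·ρ/M; only *ratios* of η between conditions are
physically meaningful here, so the condition of interest is divided by a
reference (pure water normalized to 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .elasticity import CONSTANTS
from .frames import MolecularFrame

__all__ = [
    "ViscosityInput",
    "RgSeries",
    "radius_of_gyration",
    "rg_series",
    "end_to_end_distance",
    "characteristic_viscosity",
    "normalized_viscosity",
]


@dataclass(frozen=True)
class ViscosityInput:
    """Inputs of the characteristic-viscosity formula.

    ``radius_of_gyration`` in Å, ``density`` of the simulation cell in
    kg/L (numerically equal to g/cm³), ``molar_mass`` in g/mol.
    """

    radius_of_gyration: float
    density: float
    molar_mass: float

    def __post_init__(self) -> None:
        if not (self.radius_of_gyration > 0 and self.density > 0 and self.molar_mass > 0):
            raise ValueError("all viscosity inputs must be strictly positive")


@dataclass
class RgSeries:
    """Per-frame R_g values with mean and standard error."""

    values: np.ndarray  # Å, one per frame
    times: np.ndarray  # ns

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if self.values.size < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / np.sqrt(self.values.size))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ns": self.times, "rg_A": self.values})


def _selection_indices(frame: MolecularFrame, role, molecule_id) -> np.ndarray:
    idx = frame.select(role=role, molecule_id=molecule_id)
    if idx.size == 0:
        raise ValueError(f"empty selection (role={role!r}, molecule_id={molecule_id!r})")
    return idx


def radius_of_gyration(
    frame: MolecularFrame,
    role: str | None = "solute",
    molecule_id: int | None = None,
) -> float:
    """Mass-weighted radius of gyration (Å) of the selected atoms.

    R_g = sqrt(Σ m_i |r_i − r_com|² / Σ m_i).  Invariant under rigid
    motions; scales linearly with the coordinates.
    """
    idx = _selection_indices(frame, role, molecule_id)
    m = frame.masses[idx]
    r = frame.positions[idx]
    com = np.average(r, axis=0, weights=m)
    d2 = np.sum((r - com) ** 2, axis=1)
    return float(np.sqrt(np.average(d2, weights=m)))


def rg_series(
    frames: list[MolecularFrame],
    role: str | None = "solute",
    molecule_id: int | None = None,
) -> RgSeries:
    """Radius of gyration over a frame series (mean ± standard error)."""
    if not frames:
        raise ValueError("need at least one frame")
    values = np.asarray([radius_of_gyration(f, role, molecule_id) for f in frames])
    times = np.asarray([f.time for f in frames])
    return RgSeries(values=values, times=times)


def end_to_end_distance(
    frame: MolecularFrame,
    molecule_id: int | None = None,
    atom_names: tuple[str, ...] | None = None,
) -> float:
    """Distance (Å) between the first and last atoms of a solute molecule.

    Endpoints default to the first/last atoms of the molecule in input
    order; ``atom_names`` optionally restricts to backbone sites (e.g.
    ``("SU",)`` for generated chains whose unit sites are so named).
    """
    idx = _selection_indices(frame, "solute", molecule_id)
    if atom_names is not None and frame.names is not None:
        mask = np.isin(frame.names[idx], atom_names)
        if mask.any():
            idx = idx[mask]
    if idx.size < 2:
        raise ValueError("molecule needs at least 2 atoms for an end-to-end distance")
    return float(np.linalg.norm(frame.positions[idx[-1]] - frame.positions[idx[0]]))


def characteristic_viscosity(inputs: ViscosityInput) -> float:
    """Characteristic viscosity η = (10π·N_A/3)·R_g³·ρ/M.

    R_g is converted to cm and ρ taken as g/cm³ (kg/L), so η comes out in
    cm³/g-scale model units; absolute values are convention-dependent and
    only ratios between conditions should be interpreted.
    """
    rg_cm = inputs.radius_of_gyration * 1e-8
    return float(
        (10.0 * np.pi * CONSTANTS.avogadro_number / 3.0)
        * rg_cm**3
        * inputs.density
        / inputs.molar_mass
    )


def normalized_viscosity(
    inputs: dict[str, ViscosityInput],
    reference: str,
) -> dict[str, float]:
    """η of each condition divided by the reference condition's η.

    The reference maps to exactly 1.0.  Raises ``KeyError`` when the
    reference condition is absent.
    """
    if reference not in inputs:
        raise KeyError(f"reference condition {reference!r} not among {sorted(inputs)}")
    eta_ref = characteristic_viscosity(inputs[reference])
    out = {name: characteristic_viscosity(vi) / eta_ref for name, vi in inputs.items()}
    out[reference] = 1.0
    return out
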