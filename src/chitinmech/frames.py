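"""Molecular frames: atoms with positions, masses, molecule ids and roles.

A :class:`MolecularFrame` is the in-memory container shared by the
conformational metrics and the hydrogen-bond analysis.  Atoms carry a
``role`` — ``solute`` (the polysaccharide chain), ``solvent`` (water) or
``ion`` (e.g. hydronium) — and a ``molecule_id`` grouping them into
molecules.  Frames can be read from PDB files (via biotite; molecule ids
from chain + residue, roles from residue names) or from the package's
extended-XYZ dialect, which additionally carries masses, molecule ids,
roles and atom names explicitly.

Positions are in Å, masses in amu, frame times in ns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "MolecularFrame",
    "read_xyz_frames",
    "write_xyz_frames",
    "read_pdb_frames",
    "read_frames",
]

ROLES = ("solute", "solvent", "ion")

# standard atomic masses (amu) for elements appearing in these systems
ELEMENT_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "NA": 22.990,
    "CL": 35.45,
    "S": 32.06,
    "P": 30.974,
}

_WATER_RESIDUES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC"}
_ION_RESIDUES = {"NA", "CL", "K", "MG", "CA", "H3O", "HYD", "OH"}


@dataclass
class MolecularFrame:
    """One molecular configuration.

    ``bonds`` is an optional list of covalent (i, j) atom-index pairs; when
    absent, hydrogen–heavy-atom bonding is inferred geometrically where
    needed.  ``names`` are free-form atom labels (e.g. ``SU`` for a
    saccharide-unit site, ``OW`` for a water oxygen).
    """

    positions: np.ndarray  # (n, 3) Å
    masses: np.ndarray  # (n,) amu
    elements: np.ndarray  # (n,) str
    molecule_ids: np.ndarray  # (n,) int
    roles: np.ndarray  # (n,) str in ROLES
    names: np.ndarray | None = None
    bonds: list[tuple[int, int]] | None = None
    time: float = 0.0  # ns

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        self.masses = np.asarray(self.masses, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.names is not None:
            self.names = np.asarray(self.names, dtype=object)
        for arr, label in (
            (self.masses, "masses"),
            (self.elements, "elements"),
            (self.molecule_ids, "molecule_ids"),
            (self.roles, "roles"),
        ):
            if arr.shape != (n,):
                raise ValueError(f"{label} must have shape ({n},)")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        unknown = set(self.roles) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles: {sorted(unknown)}")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def select(self, role: str | None = None, molecule_id: int | None = None) -> np.ndarray:
        """Indices of atoms matching the given role and/or molecule id."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if molecule_id is not None:
            mask &= self.molecule_ids == molecule_id
        return np.flatnonzero(mask)

    def transformed(self, rotation: np.ndarray | None = None, translation=None) -> "MolecularFrame":
        """Copy with a rigid motion applied (for invariance checks)."""
        pos = self.positions
        if rotation is not None:
            pos = pos @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            pos = pos + np.asarray(translation, dtype=float)
        return MolecularFrame(
            positions=pos,
            masses=self.masses.copy(),
            elements=self.elements.copy(),
            molecule_ids=self.molecule_ids.copy(),
            roles=self.roles.copy(),
            names=None if self.names is None else self.names.copy(),
            bonds=None if self.bonds is None else list(self.bonds),
            time=self.time,
        )


# ---------------------------------------------------------------------------
# Extended XYZ dialect
#
#   <n_atoms>
#   time_ns=<t> [bonds=i-j,i-j,...]
#   <element> <x> <y> <z> <mass> <molecule_id> <role> [name]
#   ... (repeated per frame for multi-frame files)
# ---------------------------------------------------------------------------


def write_xyz_frames(frames: list[MolecularFrame], path) -> None:
    """Write frames in the package extended-XYZ dialect."""
    lines: list[str] = []
    for frame in frames:
        lines.append(str(frame.n_atoms))
        comment = f"time_ns={frame.time!r}"
        if frame.bonds:
            comment += " bonds=" + ",".join(f"{i}-{j}" for i, j in frame.bonds)
        lines.append(comment)
        names = frame.names if frame.names is not None else [""] * frame.n_atoms
        for i in range(frame.n_atoms):
            x, y, z = frame.positions[i]
            lines.append(
                f"{frame.elements[i]} {float(x)!r} {float(y)!r} {float(z)!r} {float(frame.masses[i])!r} "
                f"{frame.molecule_ids[i]} {frame.roles[i]} {names[i]}".rstrip()
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz_frames(path) -> list[MolecularFrame]:
    """Read one or more frames from the package extended-XYZ dialect."""
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularFrame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"line {i + 1}: expected an atom count") from exc
        fields = dict(
            item.split("=", 1) for item in lines[i + 1].split() if "=" in item
        )
        time = float(fields.get("time_ns", 0.0))
        bonds = None
        if "bonds" in fields and fields["bonds"]:
            bonds = [tuple(int(v) for v in pair.split("-")) for pair in fields["bonds"].split(",")]
        rows = lines[i + 2 : i + 2 + n]
        if len(rows) < n:
            raise ValueError(f"line {i + 1}: frame truncated (expected {n} atoms)")
        elements, pos, masses, mol_ids, roles, names = [], [], [], [], [], []
        for k, row in enumerate(rows):
            parts = row.split()
            if len(parts) < 7:
                raise ValueError(f"line {i + 3 + k}: expected ≥ 7 columns")
            elements.append(parts[0])
            pos.append([float(parts[1]), float(parts[2]), float(parts[3])])
            masses.append(float(parts[4]))
            mol_ids.append(int(parts[5]))
            roles.append(parts[6])
            names.append(parts[7] if len(parts) > 7 else "")
        frames.append(
            MolecularFrame(
                positions=np.asarray(pos),
                masses=np.asarray(masses),
                elements=np.asarray(elements, dtype=object),
                molecule_ids=np.asarray(mol_ids),
                roles=np.asarray(roles, dtype=object),
                names=np.asarray(names, dtype=object),
                bonds=bonds,
                time=time,
            )
        )
        i += 2 + n
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return frames


# ---------------------------------------------------------------------------
# PDB input (via biotite)
# ---------------------------------------------------------------------------


def _role_for_residue(res_name: str) -> str:
    name = res_name.strip().upper()
    if name in _WATER_RESIDUES:
        return "solvent"
    if name in _ION_RESIDUES:
        return "ion"
    return "solute"


def read_pdb_frames(path) -> list[MolecularFrame]:
    """Read frames from a PDB file.

    Molecule ids are assigned by enumerating distinct (chain, residue id)
    pairs for solvent/ions and distinct chains for solute; roles come from
    residue names (water residues → solvent, common ions/hydronium → ion,
    everything else → solute).  Masses are standard atomic masses by
    element.
    """
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    structure = pdb_file.get_structure()  # AtomArrayStack
    frames: list[MolecularFrame] = []
    for model_idx in range(structure.stack_depth()):
        atoms = structure[model_idx]
        n = atoms.array_length()
        elements = np.asarray([e.upper() for e in atoms.element], dtype=object)
        try:
            masses = np.asarray([ELEMENT_MASSES[e] for e in elements])
        except KeyError as exc:
            raise ValueError(f"no standard mass for element {exc.args[0]!r}") from exc
        roles = np.asarray([_role_for_residue(r) for r in atoms.res_name], dtype=object)
        mol_ids = np.empty(n, dtype=int)
        key_to_id: dict = {}
        for i in range(n):
            # solute molecules are whole chains; solvent/ion molecules are residues
            key = (atoms.chain_id[i],) if roles[i] == "solute" else (
                atoms.chain_id[i],
                int(atoms.res_id[i]),
                "s",
            )
            mol_ids[i] = key_to_id.setdefault(key, len(key_to_id))
        frames.append(
            MolecularFrame(
                positions=np.asarray(atoms.coord, dtype=float),
                masses=masses,
                elements=elements,
                molecule_ids=mol_ids,
                roles=roles,
                names=np.asarray(atoms.atom_name, dtype=object),
                bonds=None,
                time=float(model_idx),
            )
        )
    return frames


def read_frames(path) -> list[MolecularFrame]:
    """Dispatch on file extension: .pdb → PDB reader, otherwise extended XYZ."""
    suffix = Path(path).suffix.lower()
    if suffix == ".pdb":
        return read_pdb_frames(path)
    return read_xyz_frames(path)
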