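"""Geometric hydrogen-bond detection and intra/intermolecular classification.

A hydrogen bond is scored between a donor heavy atom D (N or O carrying a
covalently bonded hydrogen H) and an acceptor heavy atom A (any N or O)
when the D···A distance is within a cutoff and the D–H···A angle is
sufficiently straight.  Bonds are classified as *intramolecular* (donor and
acceptor both in the same solute molecule) or *intermolecular* (solute on
exactly one side, or two distinct solute molecules); solvent–solvent bonds
are detected but excluded from both counts.  The inter:intra ratio over a
frame series tracks chain hydration: many solute–water bonds mean a spread,
hydrated chain, while a dominance of internal bonds accompanies collapse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .frames import MolecularFrame

__all__ = [
    "HBondCriteria",
    "HBondRecord",
    "HBondStats",
    "detect_hbonds",
    "classify_hbonds",
    "hbond_ratio_over_frames",
]

_DONOR_ELEMENTS = {"N", "O"}
_H_BOND_MAX = 1.3  # Å, covalent H–heavy bond cutoff for inference


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: D···A distance cutoff (Å) and minimum D–H···A angle (°)."""

    max_da_distance: float = 3.5
    min_dha_angle: float = 130.0

    def __post_init__(self) -> None:
        if not self.max_da_distance > 0:
            raise ValueError("max_da_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ValueError("min_dha_angle must lie in (0, 180]")


@dataclass(frozen=True)
class HBondRecord:
    """One detected hydrogen bond (atom indices into the source frame)."""

    donor: int
    hydrogen: int
    acceptor: int
    distance: float  # Å, D···A
    angle: float  # degrees, D–H···A
    kind: str  # "intra" | "inter" | "solvent"


@dataclass
class HBondStats:
    """Intra/inter counts averaged over a frame series."""

    per_frame: pd.DataFrame  # columns: time_ns, intra, inter
    mean_intra: float
    mean_inter: float
    ratio: float  # inter / intra; inf when mean_intra == 0


def _donor_hydrogen_pairs(frame: MolecularFrame) -> list[tuple[int, int]]:
    """(donor, hydrogen) pairs from explicit bonds, else geometric inference."""
    h_idx = np.flatnonzero(frame.elements == "H")
    if h_idx.size == 0:
        return []
    pairs: list[tuple[int, int]] = []
    if frame.bonds:
        bonded: dict[int, list[int]] = {}
        for i, j in frame.bonds:
            bonded.setdefault(i, []).append(j)
            bonded.setdefault(j, []).append(i)
        for h in h_idx:
            partners = [p for p in bonded.get(int(h), []) if frame.elements[p] in _DONOR_ELEMENTS]
            if not partners:
                raise ValueError(
                    f"hydrogen atom {h} has no bonded N/O donor; supply a complete "
                    "bond list on the frame"
                )
            # a hydrogen has exactly one covalent heavy partner
            pairs.append((partners[0], int(h)))
        return pairs
    heavy_idx = np.flatnonzero(np.isin(frame.elements, list(_DONOR_ELEMENTS)))
    if heavy_idx.size == 0:
        raise ValueError("frame has hydrogens but no N/O atoms to bond them to; supply bonds")
    tree = cKDTree(frame.positions[heavy_idx])
    dist, nearest = tree.query(frame.positions[h_idx])
    for h, d, k in zip(h_idx, dist, nearest):
        if d > _H_BOND_MAX:
            raise ValueError(
                f"hydrogen atom {int(h)} has no N/O within {_H_BOND_MAX} Å; supply an "
                "explicit bond list on the frame"
            )
        pairs.append((int(heavy_idx[k]), int(h)))
    return pairs


def _classify(frame: MolecularFrame, donor: int, acceptor: int) -> str:
    d_solute = frame.roles[donor] == "solute"
    a_solute = frame.roles[acceptor] == "solute"
    if not (d_solute or a_solute):
        return "solvent"
    if d_solute and a_solute and frame.molecule_ids[donor] == frame.molecule_ids[acceptor]:
        return "intra"
    return "inter"


def detect_hbonds(
    frame: MolecularFrame,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBondRecord]:
    """All hydrogen bonds in a frame satisfying the geometric criteria.

    Donors are N/O heavy atoms with a covalently bonded hydrogen (explicit
    bonds when present, otherwise inferred from H–heavy distances below
    1.3 Å); acceptors are all N/O atoms.  The acceptor may not be the donor
    itself nor covalently bonded to the donor or its hydrogen.  Records are
    ordered deterministically by (donor, acceptor) index.
    """
    pairs = _donor_hydrogen_pairs(frame)
    if not pairs:
        return []
    covalent: set[tuple[int, int]] = set()
    if frame.bonds:
        for i, j in frame.bonds:
            covalent.add((i, j))
            covalent.add((j, i))
    for d, h in pairs:
        covalent.add((d, h))
        covalent.add((h, d))

    acceptor_idx = np.flatnonzero(np.isin(frame.elements, list(_DONOR_ELEMENTS)))
    tree = cKDTree(frame.positions[acceptor_idx])
    records: list[HBondRecord] = []
    for donor, hydrogen in pairs:
        neighbors = tree.query_ball_point(frame.positions[donor], criteria.max_da_distance)
        for k in neighbors:
            acceptor = int(acceptor_idx[k])
            if acceptor == donor or acceptor == hydrogen:
                continue
            if (donor, acceptor) in covalent or (hydrogen, acceptor) in covalent:
                continue
            vec_d = frame.positions[donor] - frame.positions[hydrogen]
            vec_a = frame.positions[acceptor] - frame.positions[hydrogen]
            cos = np.dot(vec_d, vec_a) / (np.linalg.norm(vec_d) * np.linalg.norm(vec_a))
            angle = float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
            if angle < criteria.min_dha_angle:
                continue
            distance = float(np.linalg.norm(frame.positions[acceptor] - frame.positions[donor]))
            records.append(
                HBondRecord(
                    donor=donor,
                    hydrogen=hydrogen,
                    acceptor=acceptor,
                    distance=distance,
                    angle=angle,
                    kind=_classify(frame, donor, acceptor),
                )
            )
    records.sort(key=lambda r: (r.donor, r.acceptor))
    return records


def classify_hbonds(records: list[HBondRecord]) -> tuple[int, int]:
    """(intra, inter) counts; solvent–solvent records are excluded from both."""
    intra = sum(1 for r in records if r.kind == "intra")
    inter = sum(1 for r in records if r.kind == "inter")
    return intra, inter


def hbond_ratio_over_frames(
    frames: list[MolecularFrame],
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondStats:
    """Mean intra/inter counts over frames and the inter:intra ratio.

    The ratio is reported as inter/intra; when the mean intramolecular
    count is zero it is flagged infinite rather than raising.
    """
    if not frames:
        raise ValueError("need at least one frame")
    rows = []
    for frame in frames:
        intra, inter = classify_hbonds(detect_hbonds(frame, criteria))
        rows.append({"time_ns": frame.time, "intra": intra, "inter": inter})
    table = pd.DataFrame(rows)
    mean_intra = float(table["intra"].mean())
    mean_inter = float(table["inter"].mean())
    ratio = float("inf") if mean_intra == 0 else mean_inter / mean_intra
    return HBondStats(per_frame=table, mean_intra=mean_intra, mean_inter=mean_inter, ratio=ratio)
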