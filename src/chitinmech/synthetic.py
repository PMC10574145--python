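"""Synthetic data generators: SMFS retraction curves and solvated chains.

The curve generator emulates single-molecule force-spectroscopy retraction
traces: an adhesion spike near zero extension, an entropic-to-enthalpic
elastic rise following the two-state FJC forward model (with per-curve
contour-length variation, as every picked-up chain has a different
molecular weight), additive Gaussian force noise, and an abrupt detachment
at a set rupture force followed by a short baseline tail.

The frame generator emulates a solvated single chain: a freely rotating
chain of saccharide-unit sites whose compactness is controlled by a single
parameter κ (0 = extended, 1 = collapsed globule), decorated with an exact
number of bridging waters (each hydrogen-bonded to two adjacent units),
optional internal donor groups (intramolecular hydrogen bonds), and bulk
waters.  Placement is constructed to satisfy the default hydrogen-bond
criteria, so detected counts are controllable ground truth.

Everything is deterministic from the spec seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng

from .curves import ForceExtensionCurve
from .elasticity import TwoStateParameters, invert_extension_to_force, tsqm_fjc_extension
from .frames import MolecularFrame

__all__ = [
    "SyntheticCurveSpec",
    "SyntheticFrameSpec",
    "generate_fec",
    "generate_chain_frame",
    "generate_frame_series",
]

_WATER_OH = 0.96  # Å
_WATER_ANGLE = 104.5  # degrees, bulk water H-O-H
_UNIT_MASS = 203.0  # amu, GlcNAc residue


@dataclass(frozen=True)
class SyntheticCurveSpec:
    """Parameters of the SMFS curve generator.

    ``n_units`` is the nominal saccharide count N (contour length
    L0 = N·l_u); each curve samples its own N uniformly within
    ±``n_units_jitter`` of nominal.  ``force_noise`` is the Gaussian force
    noise σ in pN.  ``detachment_force`` may be a single value or a
    (low, high) range sampled per curve; it must exceed the 1500 pN
    normalization reference for curves meant to be normalizable.
    """

    params: TwoStateParameters = TwoStateParameters()
    n_units: int = 50
    n_units_jitter: float = 0.2
    force_noise: float = 10.0
    adhesion_height: float = 300.0
    adhesion_width: float = 5.0  # nm
    detachment_force: float | tuple[float, float] = 1800.0
    samples_per_curve: int = 400
    n_curves: int = 20
    tail_samples: int = 5
    seed: int = 0
    environment: str = "DI"

    def __post_init__(self) -> None:
        if self.n_units < 10:
            raise ValueError("n_units must be ≥ 10")
        if self.force_noise < 0:
            raise ValueError("force_noise must be ≥ 0")
        if self.samples_per_curve < 20 or self.n_curves < 1:
            raise ValueError("need ≥ 20 samples per curve and ≥ 1 curve")
        lo = self.detachment_force if np.isscalar(self.detachment_force) else self.detachment_force[0]
        if lo <= 0:
            raise ValueError("detachment force must be positive")


def generate_fec(spec: SyntheticCurveSpec) -> list[ForceExtensionCurve]:
    """Generate a reproducible ensemble of synthetic retraction curves.

    Each curve records generator ground truth in its metadata:
    ``truth_n_units``, ``truth_detachment_force_pN``,
    ``truth_adhesion_end_index`` (first sample past the adhesion spike) and
    ``truth_detachment_index`` (first post-rupture baseline sample).
    """
    children = SeedSequence(spec.seed).spawn(spec.n_curves)
    p = spec.params
    curves: list[ForceExtensionCurve] = []
    # the fractional-extension grid linspace(0, z_max) is the same for every
    # curve, so the model inversion is shared across the ensemble
    force_cache: dict[float, np.ndarray] = {}

    def force_on_grid(f_det: float) -> np.ndarray:
        if f_det not in force_cache:
            z_max = tsqm_fjc_extension(f_det, p)
            z_grid = np.linspace(0.0, z_max, spec.samples_per_curve)
            force_cache[f_det] = np.array(
                [invert_extension_to_force(z, p) for z in z_grid]
            )
        return force_cache[f_det]

    for k, child in enumerate(children):
        rng = default_rng(child)
        lo, hi = 1.0 - spec.n_units_jitter, 1.0 + spec.n_units_jitter
        n_units = max(10, int(round(rng.uniform(lo * spec.n_units, hi * spec.n_units))))
        contour = n_units * p.unit_length_free
        if np.isscalar(spec.detachment_force):
            f_det = float(spec.detachment_force)
        else:
            f_det = float(rng.uniform(*spec.detachment_force))
        z_max = tsqm_fjc_extension(f_det, p)
        extension = np.linspace(0.0, contour * z_max, spec.samples_per_curve)
        force = force_on_grid(f_det).copy()
        # triangular adhesion spike on top of the elastic response
        w, h = spec.adhesion_width, spec.adhesion_height
        spike = np.clip(h * (1.0 - np.abs(extension - w / 2.0) / (w / 2.0)), 0.0, None)
        force = force + spike
        adhesion_end = int(np.searchsorted(extension, w))
        # post-rupture baseline tail
        dx = extension[1] - extension[0]
        tail_x = extension[-1] + dx * np.arange(1, spec.tail_samples + 1)
        tail_f = np.zeros(spec.tail_samples)
        extension = np.concatenate([extension, tail_x])
        force = np.concatenate([force, tail_f])
        if spec.force_noise > 0:
            force = force + rng.normal(0.0, spec.force_noise, size=force.size)
        curves.append(
            ForceExtensionCurve(
                extension=extension,
                force=force,
                curve_id=f"{spec.environment}_{k:03d}",
                environment=spec.environment,
                pulling_velocity=2.0,
                metadata={
                    "truth_n_units": str(n_units),
                    "truth_detachment_force_pN": repr(f_det),
                    "truth_adhesion_end_index": str(adhesion_end),
                    "truth_detachment_index": str(spec.samples_per_curve),
                },
            )
        )
    return curves


@dataclass(frozen=True)
class SyntheticFrameSpec:
    """Parameters of the solvated-chain frame generator.

    ``compactness`` κ ∈ [0, 1] spans the morphology axis from an extended
    free chain (κ = 0) to a collapsed globule (κ = 1).  ``bridge_waters``
    waters are each placed to hydrogen-bond to two adjacent chain units
    (2 intermolecular bonds per bridge); ``intra_hbonds`` internal donor
    groups each form one intramolecular bond; ``bulk_waters`` and
    ``ion_waters`` (hydronium-like, role "ion") are placed uniformly with a
    2 Å minimum-distance rejection rule.
    """

    n_units: int = 10
    bond_length: float = 4.5  # Å, unit-site spacing
    compactness: float = 0.5
    bridge_waters: int = 0
    intra_hbonds: int = 0
    bulk_waters: int = 0
    ion_waters: int = 0
    box_size: float = 30.0  # Å
    n_frames: int = 1
    seed: int = 0
    unit_mass: float = _UNIT_MASS

    def __post_init__(self) -> None:
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if not 0.0 <= self.compactness <= 1.0:
            raise ValueError("compactness must lie in [0, 1]")
        if min(self.bridge_waters, self.intra_hbonds, self.bulk_waters, self.ion_waters) < 0:
            raise ValueError("counts must be ≥ 0")
        if self.n_units < 2:
            raise ValueError("n_units must be ≥ 2")
        if self.bridge_waters > self.n_units - 1:
            raise ValueError("at most n_units − 1 bridging waters (one per adjacent pair)")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _chain_positions(spec: SyntheticFrameSpec, rng) -> np.ndarray:
    """Freely rotating chain with κ-controlled directional persistence and
    a κ-shrinking soft confinement sphere."""
    n, b, kappa = spec.n_units, spec.bond_length, spec.compactness
    r_conf = max(1.3 * b * n ** (1.0 / 3.0), (1.0 - kappa) * n * b)
    wiggle = 0.05 + 2.5 * kappa  # angular diffusivity of the step direction
    pos = np.zeros((n, 3))
    direction = _random_unit(rng)
    for i in range(1, n):
        for _ in range(200):
            proposal = direction + wiggle * rng.normal(size=3)
            proposal /= np.linalg.norm(proposal)
            candidate = pos[i - 1] + b * proposal
            if np.linalg.norm(candidate) <= r_conf:
                pos[i] = candidate
                direction = proposal
                break
        else:
            raise RuntimeError("chain placement failed; increase the box/confinement size")
    return pos


def _perpendicular_dirs(axis: np.ndarray, rng, tries: int) :
    axis = axis / np.linalg.norm(axis)
    for _ in range(tries):
        v = rng.normal(size=3)
        v -= axis * np.dot(v, axis)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            yield v / norm


def generate_chain_frame(spec: SyntheticFrameSpec, rng=None, time: float = 0.0) -> MolecularFrame:
    """Generate one solvated-chain frame; deterministic from the spec seed.

    Atom ordering: chain unit sites (name ``SU``) first, then internal
    donor groups (``SOD``/``SHD``, same molecule as the chain), then
    bridging waters, bulk waters and ion waters (``OW``/``HW1``/``HW2``,
    one molecule id each).  Raises ``RuntimeError`` when a placement cannot
    be found after bounded retries (suggesting a larger box).
    """
    if rng is None:
        rng = default_rng(SeedSequence(spec.seed))
    units = _chain_positions(spec, rng)
    n = spec.n_units

    positions: list[np.ndarray] = [u for u in units]
    elements = ["O"] * n  # unit sites act as hydrogen-bond acceptors
    masses = [spec.unit_mass] * n
    mol_ids = [0] * n
    roles = ["solute"] * n
    names = ["SU"] * n
    bonds: list[tuple[int, int]] = [(i - 1, i) for i in range(1, n)]

    def clearance(
        point: np.ndarray,
        min_dist: float,
        exempt: set[int] = frozenset(),
        heavy_only: bool = False,
    ) -> bool:
        for idx, q in enumerate(positions):
            if idx in exempt or (heavy_only and elements[idx] == "H"):
                continue
            if np.linalg.norm(point - q) < min_dist:
                return False
        return True

    def add_atom(point, element, mass, mol, role, name) -> int:
        positions.append(np.asarray(point, dtype=float))
        elements.append(element)
        masses.append(mass)
        mol_ids.append(mol)
        roles.append(role)
        names.append(name)
        return len(positions) - 1

    # internal donor groups: side O–H of unit i aimed at the unit-(i+1) site
    if spec.intra_hbonds > n - 1:
        raise ValueError("at most n_units − 1 internal hydrogen bonds")
    intra_pairs = [(j, j + 1) for j in range(spec.intra_hbonds)]
    for i_unit, a_unit in intra_pairs:
        acc = units[a_unit]
        placed = False
        axis = units[a_unit] - units[i_unit]
        for u in _perpendicular_dirs(axis, rng, 400):
            od = acc + 2.9 * u
            if not clearance(od, 3.6, exempt={a_unit}, heavy_only=True):
                continue
            hd = od - _WATER_OH * u  # H between donor O and acceptor, angle 180°
            od_idx = add_atom(od, "O", 17.007, 0, "solute", "SOD")
            hd_idx = add_atom(hd, "H", 1.008, 0, "solute", "SHD")
            bonds.append((od_idx, hd_idx))
            placed = True
            break
        if not placed:
            raise RuntimeError("could not place an internal donor group; increase the box size")

    # bridging waters: O equidistant (3.0 Å) from two adjacent unit sites,
    # hydrogens pointing at each site so both D–H···A angles are 180°
    next_mol = 1
    n_bridges = 0
    for pair in rng.permutation(n - 1):
        if n_bridges == spec.bridge_waters:
            break
        a, c = units[pair], units[pair + 1]
        mid = 0.5 * (a + c)
        half = np.linalg.norm(c - a) / 2.0
        d_target = 3.0
        if half >= d_target:
            raise RuntimeError("unit spacing too wide for a 3.0 Å bridge")
        height = np.sqrt(d_target**2 - half**2)
        for u in _perpendicular_dirs(c - a, rng, 400):
            ow = mid + height * u
            # the bridge O may approach only its two target units
            if not clearance(ow, 3.6, exempt={int(pair), int(pair) + 1}, heavy_only=True):
                continue
            if not clearance(ow, 2.0, exempt={int(pair), int(pair) + 1}):
                continue
            h1 = ow + _WATER_OH * (a - ow) / np.linalg.norm(a - ow)
            h2 = ow + _WATER_OH * (c - ow) / np.linalg.norm(c - ow)
            ow_idx = add_atom(ow, "O", 15.999, next_mol, "solvent", "OW")
            h1_idx = add_atom(h1, "H", 1.008, next_mol, "solvent", "HW1")
            h2_idx = add_atom(h2, "H", 1.008, next_mol, "solvent", "HW2")
            bonds.extend([(ow_idx, h1_idx), (ow_idx, h2_idx)])
            next_mol += 1
            n_bridges += 1
            break
    if n_bridges < spec.bridge_waters:
        raise RuntimeError("could not place all bridging waters; increase the box size")

    # bulk and ion waters: rigid 3-point geometry, uniform placement with
    # a 2 Å minimum-distance rejection rule
    center = units.mean(axis=0)
    half_box = spec.box_size / 2.0
    theta = np.radians(_WATER_ANGLE)
    for count, role in ((spec.bulk_waters, "solvent"), (spec.ion_waters, "ion")):
        for _ in range(count):
            for _attempt in range(2000):
                ow = center + rng.uniform(-half_box, half_box, size=3)
                if not clearance(ow, 2.0):
                    continue
                e1 = _random_unit(rng)
                ref = _random_unit(rng)
                e2 = ref - e1 * np.dot(ref, e1)
                e2 /= np.linalg.norm(e2)
                h1 = ow + _WATER_OH * e1
                h2 = ow + _WATER_OH * (np.cos(theta) * e1 + np.sin(theta) * e2)
                break
            else:
                raise RuntimeError("could not place a bulk water; increase the box size")
            ow_idx = add_atom(ow, "O", 15.999, next_mol, role, "OW")
            h1_idx = add_atom(h1, "H", 1.008, next_mol, role, "HW1")
            h2_idx = add_atom(h2, "H", 1.008, next_mol, role, "HW2")
            bonds.extend([(ow_idx, h1_idx), (ow_idx, h2_idx)])
            next_mol += 1

    return MolecularFrame(
        positions=np.asarray(positions),
        masses=np.asarray(masses),
        elements=np.asarray(elements, dtype=object),
        molecule_ids=np.asarray(mol_ids),
        roles=np.asarray(roles, dtype=object),
        names=np.asarray(names, dtype=object),
        bonds=bonds,
        time=time,
    )


def generate_frame_series(spec: SyntheticFrameSpec) -> list[MolecularFrame]:
    """Independent frames from per-frame seeds derived from the master seed.

    Frame times span 0–20 ns (uniform spacing), mirroring a short
    data-collection trajectory.
    """
    children = SeedSequence(spec.seed).spawn(spec.n_frames)
    span = 20.0
    times = (
        np.linspace(0.0, span, spec.n_frames) if spec.n_frames > 1 else np.array([0.0])
    )
    return [
        generate_chain_frame(spec, rng=default_rng(child), time=float(t))
        for child, t in zip(children, times)
    ]
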