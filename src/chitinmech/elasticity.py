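"""Entropic and two-state elasticity models for polysaccharide stretching.

The freely jointed chain (FJC) describes the entropic elasticity of a
flexible polymer: the fractional end-to-end extension under a force ``F``
follows the Langevin function of ``F l_k / k_B T``, where ``l_k`` is the
Kuhn length.  For a 1,4-linked polysaccharide such as chitin, each
saccharide unit can additionally occupy one of two conformational states: a
short, water-bridged state of length ``l_u`` and a long, force-stretched
state of length ``l_f``.  The free-energy gap between the states, ``ΔG``
(per unit, in multiples of the thermal energy), is tilted by the mechanical
work ``F ΔL`` with ``ΔL = l_f − l_u``, so the population of the long state
follows a Fermi (two-state Boltzmann) weight.  The resulting two-state FJC
(TSQM-FJC) extension is the FJC extension scaled by the population-averaged
unit length.

Units: forces in pN, lengths in nm, energies per unit in multiples of
``k_B T`` unless stated otherwise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

__all__ = [
    "PhysicalConstants",
    "TwoStateParameters",
    "CONSTANTS",
    "UnreachableExtensionError",
    "fjc_extension",
    "effective_unit_length",
    "state_populations",
    "tsqm_fjc_extension",
    "transition_force",
    "invert_extension_to_force",
    "convert_energy",
]


class UnreachableExtensionError(ValueError):
    """Requested fractional extension lies at/above the model supremum."""


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants and unit-conversion conventions.

    Attributes
    ----------
    boltzmann_constant:
        Boltzmann constant in pN·nm/K.
    avogadro_number:
        Avogadro constant, 1/mol.
    kj_mol_per_kbt:
        Reporting conversion factor between per-unit energies in k_BT and
        kJ/mol.  The exact value at 298 K is 2.478 kJ/mol, but per-unit free
        energies in this field are conventionally reported with a rounded
        factor of 2.5 (e.g. 1.50 k_BT/unit ↔ 3.75 kJ/(mol·unit)); mechanics
        always uses the exact ``boltzmann_constant``.
    default_temperature:
        Default absolute temperature, K (room temperature).
    """

    boltzmann_constant: float = 0.0138065
    avogadro_number: float = 6.02214076e23
    kj_mol_per_kbt: float = 2.5
    default_temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in ("boltzmann_constant", "avogadro_number", "kj_mol_per_kbt", "default_temperature"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    def thermal_energy(self, temperature: float | None = None) -> float:
        """k_B·T in pN·nm at ``temperature`` (default: room temperature)."""
        t = self.default_temperature if temperature is None else temperature
        if t <= 0:
            raise ValueError("temperature must be positive")
        return self.boltzmann_constant * t


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class TwoStateParameters:
    """Parameters of the two-state FJC model for a saccharide chain.

    Attributes
    ----------
    kuhn_length:
        Kuhn segment length l_k, nm (0.514 nm for chitin).
    unit_length_free:
        Saccharide unit length l_u in the free (water-bridged) state, nm.
    unit_length_forced:
        Unit length l_f under high force, nm.
    bridge_energy:
        ΔG, free energy of the bridged (short) state per unit, in k_BT.
        This is the hydration-strength readout of the model.
    temperature:
        Absolute temperature, K.
    backbone_modulus:
        Optional linear backbone stretch modulus K_seg in pN.  ``None``
        means an inextensible backbone, L(F) = L0; otherwise
        L(F)/L0 = 1 + F/K_seg.
    constants:
        Physical constants / conversion conventions.
    """

    kuhn_length: float = 0.514
    unit_length_free: float = 0.45
    unit_length_forced: float = 0.54
    bridge_energy: float = 1.50
    temperature: float = 298.0
    backbone_modulus: float | None = None
    constants: PhysicalConstants = CONSTANTS

    def __post_init__(self) -> None:
        if not self.kuhn_length > 0:
            raise ValueError("kuhn_length must be positive")
        if not 0 < self.unit_length_free < self.unit_length_forced:
            raise ValueError("require unit_length_forced > unit_length_free > 0")
        if not np.isfinite(self.bridge_energy):
            raise ValueError("bridge_energy must be finite")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        if self.backbone_modulus is not None and not self.backbone_modulus > 0:
            raise ValueError("backbone_modulus must be positive when given")

    @property
    def delta_length(self) -> float:
        """ΔL = l_f − l_u, nm (always > 0 by construction)."""
        return self.unit_length_forced - self.unit_length_free

    @property
    def thermal_energy(self) -> float:
        """k_B·T in pN·nm at this parameter set's temperature."""
        return self.constants.thermal_energy(self.temperature)

    def replace(self, **changes) -> "TwoStateParameters":
        return dataclasses.replace(self, **changes)


def _langevin(x: np.ndarray) -> np.ndarray:
    """Langevin function L(x) = coth(x) − 1/x, stable near 0."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-3
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out


def _as_force_array(force) -> tuple[np.ndarray, bool]:
    f = np.asarray(force, dtype=float)
    scalar = f.ndim == 0
    return np.atleast_1d(f), scalar


def fjc_extension(force, params: TwoStateParameters):
    """Fractional FJC extension R/L0 at ``force`` (pN).

    Returns ``[L(F)/L0]·[coth(F l_k/k_BT) − k_BT/(F l_k)]``; the zero-force
    limit 0 is handled by a dedicated branch.  Negative forces are a domain
    error.  Accepts scalars or arrays.
    """
    f, scalar = _as_force_array(force)
    if np.any(f < 0) or not np.all(np.isfinite(f)):
        raise ValueError("force must be finite and non-negative (pN)")
    x = f * params.kuhn_length / params.thermal_energy
    z = _langevin(x)
    if params.backbone_modulus is not None:
        z = z * (1.0 + f / params.backbone_modulus)
    return float(z[0]) if scalar else z


def state_populations(force, params: TwoStateParameters):
    """Populations (p_short, p_long) of the bridged/stretched unit states.

    The long state carries Boltzmann weight exp((F ΔL − ΔG k_BT)/k_BT); at
    ``transition_force`` the two populations are equal.
    """
    f, scalar = _as_force_array(force)
    if np.any(f < 0):
        raise ValueError("force must be non-negative (pN)")
    u = f * params.delta_length / params.thermal_energy - params.bridge_energy
    p_long = expit(u)
    p_short = expit(-u)
    if scalar:
        return float(p_short[0]), float(p_long[0])
    return p_short, p_long


def effective_unit_length(force, params: TwoStateParameters):
    """Population-averaged saccharide unit length at ``force``, nm.

    ``l_u/(1+e^{(FΔL−ΔG·k_BT)/k_BT}) + l_f/(1+e^{(ΔG·k_BT−FΔL)/k_BT})``;
    strictly within (l_u, l_f), approaching l_f at high force.
    """
    f, scalar = _as_force_array(force)
    if np.any(f < 0):
        raise ValueError("force must be non-negative (pN)")
    u = f * params.delta_length / params.thermal_energy - params.bridge_energy
    ell = params.unit_length_free * expit(-u) + params.unit_length_forced * expit(u)
    return float(ell[0]) if scalar else ell


def tsqm_fjc_extension(force, params: TwoStateParameters):
    """Two-state FJC fractional extension relative to N·l_u.

    The FJC extension scaled by ``effective_unit_length/l_u``; always
    ≥ the plain FJC extension and monotone non-decreasing in force.
    """
    f, scalar = _as_force_array(force)
    z = (effective_unit_length(f, params) / params.unit_length_free) * fjc_extension(f, params)
    return float(z[0]) if scalar else z


def transition_force(params: TwoStateParameters) -> float:
    """Force (pN) at which the two unit states are equally populated.

    Analytic midpoint ΔG·k_BT/ΔL; coincides with the shoulder-like force
    plateau seen in stretched-polysaccharide force–extension curves.
    """
    if params.delta_length <= 0:
        raise ValueError("delta_length must be positive")
    return params.bridge_energy * params.thermal_energy / params.delta_length


def invert_extension_to_force(
    z: float,
    params: TwoStateParameters,
    tolerance: float = 1e-9,
    max_force: float = 1e7,
) -> float:
    """Force (pN) producing fractional two-state extension ``z``.

    Bracketed root find (Brent); the returned F satisfies
    ``|tsqm_fjc_extension(F) − z| ≤ tolerance``.  Raises
    :class:`UnreachableExtensionError` when ``z`` is at/above the model
    supremum (l_f/l_u for an inextensible backbone).
    """
    z = float(z)
    if z < 0:
        raise ValueError("fractional extension must be non-negative")
    if z == 0.0:
        return 0.0
    hi = 100.0
    while tsqm_fjc_extension(hi, params) < z:
        hi *= 4.0
        if hi > max_force:
            if tsqm_fjc_extension(max_force, params) < z:
                raise UnreachableExtensionError(
                    f"extension z={z:g} is at/above the model supremum "
                    f"(l_f/l_u = {params.unit_length_forced / params.unit_length_free:g} "
                    "for an inextensible backbone)"
                )
            hi = max_force
            break
    force = brentq(lambda f: tsqm_fjc_extension(f, params) - z, 0.0, hi, xtol=1e-10, rtol=8.9e-16)
    if abs(tsqm_fjc_extension(force, params) - z) > tolerance:
        raise UnreachableExtensionError(f"root find did not reach tolerance for z={z:g}")
    return float(force)


_UNIT_ALIASES = {
    "kbt": "kbt",
    "k_bt": "kbt",
    "kbt/unit": "kbt",
    "k_bt/unit": "kbt",
    "kj/mol": "kj_mol",
    "kj/(mol·unit)": "kj_mol",
    "kj/(mol*unit)": "kj_mol",
    "kj/(mol.unit)": "kj_mol",
    "pn·nm": "pn_nm",
    "pn*nm": "pn_nm",
    "pn nm": "pn_nm",
    "pn·nm/unit": "pn_nm",
    "pn*nm/unit": "pn_nm",
}


def convert_energy(
    value: float,
    from_unit: str,
    to_unit: str,
    *,
    constants: PhysicalConstants = CONSTANTS,
    temperature: float | None = None,
) -> float:
    """Convert a per-unit energy between k_BT, kJ/mol and pN·nm.

    k_BT ↔ kJ/mol uses the conventional reporting factor
    ``constants.kj_mol_per_kbt`` (2.5); k_BT ↔ pN·nm uses the exact thermal
    energy at ``temperature``.  Unknown units raise ``ValueError``.
    """

    def canon(u: str) -> str:
        key = u.strip().lower()
        if key not in _UNIT_ALIASES:
            raise ValueError(f"unknown energy unit: {u!r}")
        return _UNIT_ALIASES[key]

    src, dst = canon(from_unit), canon(to_unit)
    kbt_pn_nm = constants.thermal_energy(temperature)
    # hub unit: k_BT
    if src == "kbt":
        in_kbt = value
    elif src == "kj_mol":
        in_kbt = value / constants.kj_mol_per_kbt
    else:
        in_kbt = value / kbt_pn_nm
    if dst == "kbt":
        return in_kbt
    if dst == "kj_mol":
        return in_kbt * constants.kj_mol_per_kbt
    return in_kbt * kbt_pn_nm
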