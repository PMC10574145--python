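"""Pipeline configuration: one YAML file drives the whole workflow.

The configuration nests the model parameters, the fit configuration, the
hydrogen-bond criteria, per-environment synthetic curve specs,
per-condition frame specs and viscosity inputs.  Serialization round-trips
losslessly so a run is fully described by its config file plus a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .conformation import ViscosityInput
from .elasticity import PhysicalConstants, TwoStateParameters
from .fitting import FitConfiguration
from .hbonds import HBondCriteria
from .synthetic import SyntheticCurveSpec, SyntheticFrameSpec

__all__ = ["PipelineConfig", "default_config"]


def _params_to_dict(p: TwoStateParameters) -> dict:
    d = dataclasses.asdict(p)
    d["constants"] = dataclasses.asdict(p.constants)
    return d


def _params_from_dict(d: dict) -> TwoStateParameters:
    d = dict(d)
    constants = d.pop("constants", None)
    if constants is not None:
        d["constants"] = PhysicalConstants(**constants)
    return TwoStateParameters(**d)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a pipeline run."""

    parameters: TwoStateParameters = field(default_factory=TwoStateParameters)
    fit: FitConfiguration = field(default_factory=FitConfiguration)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    curve_specs: dict[str, SyntheticCurveSpec] = field(default_factory=dict)
    frame_specs: dict[str, SyntheticFrameSpec] = field(default_factory=dict)
    viscosity: dict[str, ViscosityInput] = field(default_factory=dict)
    viscosity_reference: str = "water"
    seed: int = 0

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        fit = dataclasses.asdict(self.fit)
        fit["base_params"] = _params_to_dict(self.fit.base_params)
        fit["force_window"] = list(self.fit.force_window)
        fit["bridge_energy_bounds"] = list(self.fit.bridge_energy_bounds)
        fit["multistart_bridge_energies"] = list(self.fit.multistart_bridge_energies)
        curve_specs = {}
        for name, spec in self.curve_specs.items():
            d = dataclasses.asdict(spec)
            d["params"] = _params_to_dict(spec.params)
            if not isinstance(spec.detachment_force, (int, float)):
                d["detachment_force"] = list(spec.detachment_force)
            curve_specs[name] = d
        return {
            "parameters": _params_to_dict(self.parameters),
            "fit": fit,
            "hbond": dataclasses.asdict(self.hbond),
            "curve_specs": curve_specs,
            "frame_specs": {n: dataclasses.asdict(s) for n, s in self.frame_specs.items()},
            "viscosity": {n: dataclasses.asdict(v) for n, v in self.viscosity.items()},
            "viscosity_reference": self.viscosity_reference,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        fit_d = dict(data.get("fit", {}))
        if "base_params" in fit_d:
            fit_d["base_params"] = _params_from_dict(fit_d["base_params"])
        for key in ("force_window", "bridge_energy_bounds", "multistart_bridge_energies"):
            if key in fit_d:
                fit_d[key] = tuple(fit_d[key])
        curve_specs = {}
        for name, d in data.get("curve_specs", {}).items():
            d = dict(d)
            if "params" in d:
                d["params"] = _params_from_dict(d["params"])
            if isinstance(d.get("detachment_force"), list):
                d["detachment_force"] = tuple(d["detachment_force"])
            curve_specs[name] = SyntheticCurveSpec(**d)
        return cls(
            parameters=_params_from_dict(data.get("parameters", {})),
            fit=FitConfiguration(**fit_d),
            hbond=HBondCriteria(**data.get("hbond", {})),
            curve_specs=curve_specs,
            frame_specs={
                n: SyntheticFrameSpec(**d) for n, d in data.get("frame_specs", {}).items()
            },
            viscosity={
                n: ViscosityInput(**d) for n, d in data.get("viscosity", {}).items()
            },
            viscosity_reference=data.get("viscosity_reference", "water"),
            seed=int(data.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))

    def write(self, path) -> None:
        Path(path).write_text(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())


# molar mass of a 10-ring chitin chain (10 GlcNAc residues + terminal water)
_CHAIN_MOLAR_MASS = 10 * 203.19 + 18.02


def default_config(seed: int = 0) -> PipelineConfig:
    """Study-condition defaults: three aqueous environments for curves
    (DI water, pH 5, pH 3 with their fitted per-unit bridge energies),
    three morphology conditions for frames spanning spread → collapsed,
    and the simulated-cell viscosity inputs."""
    base = TwoStateParameters()
    curve_specs = {
        "DI": SyntheticCurveSpec(
            params=base.replace(bridge_energy=1.50), environment="DI", seed=seed * 1000 + 1
        ),
        "pH5": SyntheticCurveSpec(
            params=base.replace(bridge_energy=3.412), environment="pH5", seed=seed * 1000 + 2
        ),
        "pH3": SyntheticCurveSpec(
            params=base.replace(bridge_energy=5.53), environment="pH3", seed=seed * 1000 + 3
        ),
    }
    frame_specs = {
        "pH3": SyntheticFrameSpec(
            n_units=10, compactness=0.1, bridge_waters=8, intra_hbonds=1,
            bulk_waters=30, box_size=40.0, n_frames=5, seed=seed * 1000 + 11,
        ),
        "water": SyntheticFrameSpec(
            n_units=10, compactness=0.5, bridge_waters=4, intra_hbonds=2,
            bulk_waters=30, box_size=40.0, n_frames=5, seed=seed * 1000 + 12,
        ),
        "pH11": SyntheticFrameSpec(
            n_units=10, compactness=0.9, bridge_waters=2, intra_hbonds=3,
            bulk_waters=30, box_size=40.0, n_frames=5, seed=seed * 1000 + 13,
        ),
    }
    viscosity = {
        "pH3": ViscosityInput(radius_of_gyration=12.27, density=0.983, molar_mass=_CHAIN_MOLAR_MASS),
        "water": ViscosityInput(radius_of_gyration=9.48, density=0.991, molar_mass=_CHAIN_MOLAR_MASS),
        "pH11": ViscosityInput(radius_of_gyration=7.0, density=0.989, molar_mass=_CHAIN_MOLAR_MASS),
    }
    return PipelineConfig(
        parameters=base,
        fit=FitConfiguration(base_params=base, seed=seed),
        curve_specs=curve_specs,
        frame_specs=frame_specs,
        viscosity=viscosity,
        viscosity_reference="water",
        seed=seed,
    )
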