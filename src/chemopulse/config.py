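"""Flat key-value parameter files and the bundled reference parameter set.

Parameter sets travel as flat mappings with keys ``D1, D2, DS, DN, alpha,
gamma1, gamma2, chi1S, chi1N, chi2S, chi2N, M1, M2`` (CGS units), stored as
YAML or JSON.  ``table1()`` returns the packaged reference set measured/
fitted for the two E. coli strains (slow/green and fast/red).
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import yaml

from .core import FieldParams, ModelParams, PopulationMix, SpeciesParams

__all__ = ["load_params", "save_params", "params_to_dict", "params_from_dict", "table1"]

_KEYS = (
    "D1",
    "D2",
    "DS",
    "DN",
    "alpha",
    "gamma1",
    "gamma2",
    "chi1S",
    "chi1N",
    "chi2S",
    "chi2N",
    "M1",
    "M2",
)


def params_from_dict(raw: dict) -> ModelParams:
    missing = [k for k in _KEYS if k not in raw]
    if missing:
        raise KeyError(f"parameter file missing keys: {missing}")
    sp1 = SpeciesParams(
        D=float(raw["D1"]),
        chi_S=float(raw["chi1S"]),
        chi_N=float(raw["chi1N"]),
        gamma=float(raw["gamma1"]),
    )
    sp2 = SpeciesParams(
        D=float(raw["D2"]),
        chi_S=float(raw["chi2S"]),
        chi_N=float(raw["chi2N"]),
        gamma=float(raw["gamma2"]),
    )
    fields = FieldParams(
        D_S=float(raw["DS"]), D_N=float(raw["DN"]), alpha=float(raw["alpha"])
    )
    mix = PopulationMix(M1=float(raw["M1"]), M2=float(raw["M2"]))
    return ModelParams(species=(sp1, sp2), fields=fields, mix=mix)


def params_to_dict(params: ModelParams) -> dict:
    sp1, sp2 = params.species
    return {
        "D1": sp1.D,
        "D2": sp2.D,
        "DS": params.fields.D_S,
        "DN": params.fields.D_N,
        "alpha": params.fields.alpha,
        "gamma1": sp1.gamma,
        "gamma2": sp2.gamma,
        "chi1S": sp1.chi_S,
        "chi1N": sp1.chi_N,
        "chi2S": sp2.chi_S,
        "chi2N": sp2.chi_N,
        "M1": params.mix.M1,
        "M2": params.mix.M2,
    }


def load_params(path: str | Path) -> ModelParams:
    """Read a parameter set from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return params_from_dict(raw)


def save_params(params: ModelParams, path: str | Path) -> None:
    """Write a parameter set as YAML (or JSON when the suffix is .json)."""
    path = Path(path)
    raw = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(raw, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(raw, sort_keys=False))


def table1(phi_red: float | None = None, total_mass: float | None = None) -> ModelParams:
    """The bundled reference parameter set for the two strains.

    Parameters
    ----------
    phi_red : float, optional
        Override the fast-population fraction (total mass preserved).
    total_mass : float, optional
        Override the total bacterial mass (line density integral, model
        units); the default is calibrated so the nutrient is consumed on
        the pulse-transit timescale.
    """
    with resources.files("chemopulse.data").joinpath("table1.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    params = params_from_dict(raw)
    if phi_red is not None or total_mass is not None:
        phi = params.phi_red if phi_red is None else phi_red
        tot = params.mix.total if total_mass is None else total_mass
        params = params.with_phi(phi, tot)
    return params
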