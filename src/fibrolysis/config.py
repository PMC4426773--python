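"""YAML configuration: geometry, conditions, solver options, sample metadata.

Every key has a documented default (the standard bagasse parameter set), so
an empty or missing file is a valid configuration.  Schema::

    geometry:
      F_hat: 0.581            # fixed lignocellulose volume fraction
      eps_N0: 0.165           # initial xylan volume fraction
      rho_s: 1500.0           # solid xylan density, kg/m^3
      N: 100                  # maximum chain length (DP)
      m: 15                   # solubility cutoff (DP)
      l: 0.65e-9              # monomer segment length, m
      R_i: 3.75e-4            # fibre radius, m
      hydrolysate_factor: 2.32  # (R_o - R_i) / R_i
      n_fibre: 100            # fibre nodes
      n_hydro: 250            # hydrolysate nodes
      D_F_inf: 1.12e-9        # furfural bulk diffusivity, m^2/s
    conditions:
      temperature_C: 110.0
      acid_mol_m3: 51.0       # bulk H3O+ concentration (0.5 wt% H2SO4)
      t_end_min: 360.0
      n_output_times: 121
    solver:
      rtol: 1.0e-7
      atol: 1.0e-10
      method: LSODA
    sample:
      dry_mass_g: 4.68
      xylan_fraction: 0.202
    composition:                # stored metadata; only xylan is consumed
      glucan: 0.438
      xylan: 0.202
      arabinan: 0.033
      lignin: 0.275
      acetyl: 0.025
      ash: 0.021
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import Optional

import numpy as np
import yaml

from .constants import SECONDS_PER_MINUTE, celsius_to_kelvin
from .experiment_io import BagasseSample
from .model_core import Conditions, MaterialGeometry

__all__ = ["Config", "DEFAULT_CONFIG", "load_config"]

DEFAULT_CONFIG = {
    "geometry": {
        "F_hat": 0.581,
        "eps_N0": 0.165,
        "rho_s": 1500.0,
        "N": 100,
        "m": 15,
        "l": 0.65e-9,
        "R_i": 3.75e-4,
        "hydrolysate_factor": 2.32,
        "n_fibre": 100,
        "n_hydro": 250,
        "D_F_inf": 1.12e-9,
    },
    "conditions": {
        "temperature_C": 110.0,
        "acid_mol_m3": 51.0,
        "t_end_min": 360.0,
        "n_output_times": 121,
    },
    "solver": {"rtol": 1e-7, "atol": 1e-10, "method": "LSODA"},
    "sample": {"dry_mass_g": 4.68, "xylan_fraction": 0.202},
    "composition": {
        "glucan": 0.438,
        "xylan": 0.202,
        "arabinan": 0.033,
        "lignin": 0.275,
        "acetyl": 0.025,
        "ash": 0.021,
    },
}


@dataclass
class Config:
    """Validated configuration resolved against the defaults."""

    geometry: MaterialGeometry
    solver: dict
    sample: BagasseSample
    composition: dict
    raw: dict

    def conditions(
        self,
        temperature_C: Optional[float] = None,
        t_end_min: Optional[float] = None,
    ) -> Conditions:
        """Build Conditions, optionally overriding temperature or horizon."""
        c = self.raw["conditions"]
        T_C = c["temperature_C"] if temperature_C is None else temperature_C
        t_end = (
            c["t_end_min"] if t_end_min is None else t_end_min
        ) * SECONDS_PER_MINUTE
        return Conditions(
            T=celsius_to_kelvin(T_C),
            C_H=c["acid_mol_m3"],
            t_end=t_end,
            output_times=np.linspace(0.0, t_end, int(c["n_output_times"])),
        )


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path=None) -> Config:
    """Load a YAML config file (or the defaults when ``path`` is None).

    Unknown top-level sections are rejected; unknown keys within known
    sections are rejected too, so typos fail loudly.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for section, values in raw.items():
        if not isinstance(values, dict):
            raise ValueError(f"config section {section!r} must be a mapping")
        bad = set(values) - set(DEFAULT_CONFIG[section])
        if bad:
            raise ValueError(
                f"unknown keys in config section {section!r}: {sorted(bad)}"
            )
    merged = _merge(DEFAULT_CONFIG, raw)
    geometry = MaterialGeometry(**merged["geometry"])
    sample = BagasseSample(
        dry_mass_g=merged["sample"]["dry_mass_g"],
        xylan_fraction=merged["sample"]["xylan_fraction"],
    )
    return Config(
        geometry=geometry,
        solver=dict(merged["solver"]),
        sample=sample,
        composition=dict(merged["composition"]),
        raw=merged,
    )
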