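"""Conversion of raw hydrolysate measurements to yields, and the tidy CSV
experiment format.

HPLC reports concentrations (g L^-1) of xylose, oligomers X2..X6 and furfural
in the drained hydrolysate.  These convert to yields as percentages of the
initial xylan mass: oligomer masses carry a water-of-hydrolysis correction
(MW - MW_H2O) / MW, and furfural mass is scaled by 132/96 to its
xylan-equivalent.  Hydrolysate volume comes from its mass via the density of
water at 25 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .constants import (
    FURFURAL_TO_XYLAN,
    MW_ANHYDROXYLOSE,
    MW_WATER,
    WATER_DENSITY_25C,
)
from .model_core import YieldSeries

__all__ = [
    "BagasseSample",
    "HydrolysateRecord",
    "SPECIES_LABELS",
    "initial_xylan_mass",
    "molecular_weight",
    "water_correction",
    "oligomer_yield",
    "furfural_yield",
    "read_experiment",
    "write_experiment",
    "ExperimentFormatError",
]

#: Recognised species labels in experiment files.
SPECIES_LABELS = ("furfural", "X1", "X2", "X3", "X4", "X5", "X6")

_CSV_COLUMNS = ["time_min", "species", "value", "value_kind"]


class ExperimentFormatError(ValueError):
    """Malformed experiment CSV; the message carries the offending line."""


@dataclass(frozen=True)
class BagasseSample:
    """Dry bagasse charge: dry mass (g) and xylan mass fraction."""

    dry_mass_g: float
    xylan_fraction: float

    def __post_init__(self) -> None:
        if self.dry_mass_g <= 0:
            raise ValueError("dry mass must be positive")
        if not 0.0 < self.xylan_fraction < 1.0:
            raise ValueError("xylan fraction must lie in (0, 1)")


@dataclass(frozen=True)
class HydrolysateRecord:
    """One sampling time: species concentrations (g L^-1) and hydrolysate mass (g)."""

    time_min: float
    concentrations_g_per_L: Dict[str, float]
    hydrolysate_mass_g: float

    def __post_init__(self) -> None:
        if self.time_min < 0:
            raise ValueError("time must be non-negative")
        if self.hydrolysate_mass_g <= 0:
            raise ValueError("hydrolysate mass must be positive")
        for label, conc in self.concentrations_g_per_L.items():
            if label not in SPECIES_LABELS:
                raise ValueError(f"unknown species label {label!r}")
            if conc < 0:
                raise ValueError(f"negative concentration for {label}")

    @property
    def volume_m3(self) -> float:
        """Hydrolysate volume (m^3), from mass via water density at 25 degC."""
        return self.hydrolysate_mass_g * 1e-3 / WATER_DENSITY_25C


def initial_xylan_mass(sample: BagasseSample) -> float:
    """Initial xylan mass X0 (g) = xylan fraction x dry bagasse mass."""
    return sample.xylan_fraction * sample.dry_mass_g


def molecular_weight(i: int) -> float:
    """Molar mass (g mol^-1) of a DP-i xylo-oligomer: i anhydroxylose units
    plus one terminal water."""
    if i < 1:
        raise ValueError("degree of polymerisation must be >= 1")
    return MW_ANHYDROXYLOSE * i + MW_WATER


def water_correction(i: int) -> float:
    """Mass factor (MW - MW_H2O)/MW removing the water of hydrolysis, so the
    measured oligomer mass is expressed on the anhydro (xylan) basis.
    Increases towards 1 with chain length."""
    mw = molecular_weight(i)
    return (mw - MW_WATER) / mw


def oligomer_yield(record: HydrolysateRecord, i: int, X0: float) -> float:
    """Yield % of a DP-i oligomer (i in 1..6) from its hydrolysate
    concentration, relative to the initial xylan mass ``X0`` (g)."""
    if not 1 <= i <= 6:
        raise ValueError("oligomer yields are defined for DP 1..6")
    if X0 <= 0:
        raise ValueError("X0 must be positive")
    conc = record.concentrations_g_per_L.get(f"X{i}", 0.0)
    mass_g = 1000.0 * conc * record.volume_m3 * water_correction(i)
    return 100.0 * mass_g / X0


def furfural_yield(record: HydrolysateRecord, X0: float) -> float:
    """Furfural yield % on the xylan-equivalent basis (mass scaled by 132/96)."""
    if X0 <= 0:
        raise ValueError("X0 must be positive")
    conc = record.concentrations_g_per_L.get("furfural", 0.0)
    mass_g = 1000.0 * conc * record.volume_m3 * FURFURAL_TO_XYLAN
    return 100.0 * mass_g / X0


# ---------------------------------------------------------------------------
# tidy CSV dialect
# ---------------------------------------------------------------------------


def write_experiment(series, path) -> None:
    """Write observations to tidy CSV (time_min, species, value, value_kind).

    ``series`` is either a :class:`~fibrolysis.model_core.YieldSeries` or an
    iterable of ``(species, time_min, yield_pct)`` triples; all rows are
    written as ``value_kind = yield_pct``.
    """
    if isinstance(series, YieldSeries):
        rows = [
            (t, label, v, "yield_pct")
            for label, values in series.yields.items()
            for t, v in zip(series.times_min, values)
        ]
    else:
        rows = [(t, s, v, "yield_pct") for s, t, v in series]
    frame = pd.DataFrame(rows, columns=_CSV_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.8g")


def read_experiment(
    path, sample: Optional[BagasseSample] = None
) -> List[Tuple[str, float, float]]:
    """Read an experiment CSV into (species, time_min, yield_pct) triples.

    Rows with ``value_kind = yield_pct`` are taken verbatim; rows with
    ``value_kind = conc_g_per_L`` additionally require a
    ``hydrolysate_mass_g`` column and a ``sample`` argument, and are
    converted through the oligomer/furfural yield formulas.
    """
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ExperimentFormatError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in _CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ExperimentFormatError(f"{path}: missing columns {missing}")

    observations: List[Tuple[str, float, float]] = []
    for row in frame.itertuples():
        line = row.Index + 2  # header is line 1
        species = str(row.species)
        if species not in SPECIES_LABELS:
            raise ExperimentFormatError(
                f"{path}:{line}: unknown species label {species!r}"
            )
        time_min = float(row.time_min)
        value = float(row.value)
        kind = str(row.value_kind)
        if not np.isfinite(value) or value < 0:
            raise ExperimentFormatError(f"{path}:{line}: invalid value {value}")
        if kind == "yield_pct":
            observations.append((species, time_min, value))
        elif kind == "conc_g_per_L":
            if sample is None:
                raise ExperimentFormatError(
                    f"{path}:{line}: concentration row needs a bagasse sample"
                )
            if "hydrolysate_mass_g" not in frame.columns or not np.isfinite(
                float(getattr(row, "hydrolysate_mass_g", np.nan))
            ):
                raise ExperimentFormatError(
                    f"{path}:{line}: concentration row needs hydrolysate_mass_g"
                )
            record = HydrolysateRecord(
                time_min=time_min,
                concentrations_g_per_L={species: value},
                hydrolysate_mass_g=float(row.hydrolysate_mass_g),
            )
            X0 = initial_xylan_mass(sample)
            if species == "furfural":
                y = furfural_yield(record, X0)
            else:
                y = oligomer_yield(record, int(species[1:]), X0)
            observations.append((species, time_min, y))
        else:
            raise ExperimentFormatError(
                f"{path}:{line}: unknown value_kind {kind!r}"
            )
    return observations
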