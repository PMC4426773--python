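"""Physical constants and unit-conversion factors.

All internal computation is SI (m, kg, s, K, mol); minutes and °C appear only
at I/O boundaries.
"""

#: Universal gas constant (J K^-1 mol^-1).
GAS_CONSTANT = 8.314

#: Boltzmann constant (m^2 kg s^-2 K^-1).
BOLTZMANN = 1.38e-23

#: Bulk diffusivity of furfural in water (m^2 s^-1).
D_FURFURAL_INF = 1.12e-9

#: Prefactor of the hydrodynamic radius of a chain, R_h(i) = 0.676 * l * sqrt(i).
HYDRODYNAMIC_PREFACTOR = 0.676

#: Molar mass of an anhydroxylose unit within a xylan chain (g mol^-1).
MW_ANHYDROXYLOSE = 132.115

#: Molar mass of water (g mol^-1).
MW_WATER = 18.02

#: Mass ratio converting furfural mass to its xylan-equivalent mass.
FURFURAL_TO_XYLAN = 132.0 / 96.0

#: Density of water at 25 °C (kg m^-3), used to convert hydrolysate mass to volume.
WATER_DENSITY_25C = 997.047

#: Zero Celsius in Kelvin.
CELSIUS_OFFSET = 273.15

SECONDS_PER_MINUTE = 60.0


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + CELSIUS_OFFSET


def kelvin_to_celsius(t_kelvin: float) -> float:
    return t_kelvin - CELSIUS_OFFSET
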