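"""Display-layer conversion between reduced and physical units.

All computation runs in reduced units (kB = 1, reference temperature
T_ref = 1); this adapter converts energies to kcal/mol and temperatures to
Kelvin for reporting, and maps the published metadynamics protocol preset
into reduced-unit parameters.
"""

from __future__ import annotations

KB_KCAL_PER_MOL_K = 0.0019872041   # Boltzmann constant, kcal / (mol K)
DEFAULT_T_KELVIN = 310.0           # physiological target temperature


def kt_in_kcal_per_mol(temperature_K: float = DEFAULT_T_KELVIN) -> float:
    return KB_KCAL_PER_MOL_K * temperature_K


def energy_to_kcal_per_mol(e_reduced: float,
                           temperature_K: float = DEFAULT_T_KELVIN) -> float:
    """Reduced energy (units of kT at T_ref) -> kcal/mol at ``temperature_K``."""
    return e_reduced * kt_in_kcal_per_mol(temperature_K)


def energy_from_kcal_per_mol(e_kcal: float,
                             temperature_K: float = DEFAULT_T_KELVIN) -> float:
    return e_kcal / kt_in_kcal_per_mol(temperature_K)


def reduced_temperature(temperature_K: float,
                        reference_K: float = DEFAULT_T_KELVIN) -> float:
    return temperature_K / reference_K


def metad_preset_reduced(preset: dict,
                         temperature_K: float = DEFAULT_T_KELVIN) -> dict:
    """Convert a unit-ful metadynamics preset to reduced-unit parameters."""
    return {
        "w0": energy_from_kcal_per_mol(preset["height_kcal_per_mol"],
                                       temperature_K),
        "sigma": preset["sigma"],
        "biasfactor": preset["biasfactor"],
        "pace": preset["pace"],
    }
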