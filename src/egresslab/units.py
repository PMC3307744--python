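"""Unit system and physical constants.

The package works throughout in AMBER-style mixed units:

========  =====================
length    Å
time      ps
energy    kcal/mol
mass      g/mol
========  =====================

In this system a force of 1 kcal·mol⁻¹·Å⁻¹ acting on 1 g/mol produces an
acceleration of ``ACC_CONV`` Å·ps⁻²; kinetic energy in kcal/mol is
``m v² / (2 ACC_CONV)``.
"""

from __future__ import annotations

#: Boltzmann constant, kcal·mol⁻¹·K⁻¹.
KB: float = 1.9872041e-3

#: (kcal·mol⁻¹·Å⁻¹) / (g·mol⁻¹)  →  Å·ps⁻².
ACC_CONV: float = 418.4

#: Bondi van der Waals radii (Å) by element symbol. Elements absent from the
#: table are assigned ``DEFAULT_VDW_RADIUS`` with a warning at parse time.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "FE": 2.00,
    "ZN": 1.39,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
    "SE": 1.90,
}

DEFAULT_VDW_RADIUS: float = 1.7


def thermal_sigma_v(mass: float, temperature: float) -> float:
    """Maxwell-Boltzmann per-component velocity standard deviation, Å/ps."""
    return (ACC_CONV * KB * temperature / mass) ** 0.5
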