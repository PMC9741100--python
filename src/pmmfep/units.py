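"""Unit conversions and physical constants.

All matrix work inside the package is done in Hartree atomic units
(Hartree, bohr, elementary charge); user-facing interfaces use Å for
lengths and kcal/mol for energies. Every conversion in the package goes
through this single constants table so that reports, profiles and logs
are mutually consistent.
"""

from __future__ import annotations

#: kcal/mol per Hartree
HARTREE_TO_KCAL: float = 627.509

#: bohr per Å
ANGSTROM_TO_BOHR: float = 1.889726

#: Boltzmann constant, Hartree / K
KB_HARTREE: float = 3.166812e-6

#: Boltzmann constant, kcal/mol / K  (kB * 300 K = 0.59616 kcal/mol)
KB_KCAL: float = KB_HARTREE * HARTREE_TO_KCAL

# Standard atomic weights (u), used for center-of-mass expansion centers.
# Masses are derived from element labels and are never user inputs.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "He": 4.0026,
    "Li": 6.94,
    "B": 10.81,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "Si": 28.085,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.38,
    "Se": 78.971,
    "Br": 79.904,
    "I": 126.904,
}


def mass_of(element: str) -> float:
    """Standard atomic weight for an element label (case-normalized)."""
    key = element.strip().capitalize()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise KeyError(f"no standard atomic mass for element label {element!r}") from None
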