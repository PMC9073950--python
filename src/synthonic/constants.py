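"""Physical constants and element data used throughout the package.

Energies are kcal/mol, distances Angstrom, charges electron units.
"""

from __future__ import annotations

#: Avogadro constant, 1/mol (2019 SI exact value).
AVOGADRO = 6.02214076e23

#: Ideal gas constant in kcal/(mol K).
R_KCAL = 1.987204258640832e-3

#: Electrostatic conversion factor k in E = k q_i q_j / (D r),
#: kcal Angstrom / (mol e^2).
COULOMB_KCAL = 332.0637

#: Covalent radii in Angstrom (single-bond values, Cordero-style set);
#: used by the bonding rule: bonded iff d < r_i + r_j + tolerance.
COVALENT_RADII = {
    "H": 0.31, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Zn": 1.22, "Br": 1.20, "I": 1.39,
}

#: Approximate atomic masses (g/mol) for the elements above.
ATOMIC_MASSES = {
    "H": 1.008, "He": 4.003,
    "Li": 6.94, "Be": 9.012, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Zn": 65.38, "Br": 79.904, "I": 126.904,
}


def known_element(symbol: str) -> bool:
    return symbol in COVALENT_RADII
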