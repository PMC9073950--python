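"""Gasteiger-Marsili partial charges (PEOE).

Iterative partial equalization of orbital electronegativity: the
electronegativity of atom i is chi_i(q) = a_i + b_i q + c_i q^2, and each
iteration n transfers, across every bond, an amount of charge

    dq = (chi_j - chi_i) / chi_plus_donor * (1/2)^n

from the less to the more electronegative partner, where chi_plus_donor is
the cation electronegativity (a + b + c) of the donor atom (20.02 for
hydrogen).  The (1/2)^n damping makes the series geometric, so charge is
conserved exactly and six or more iterations converge to ~1e-3 e.

Parameters are keyed by (element, sigma-hybridization tag).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .potential import ChargeSet

__all__ = ["assign_gasteiger_charges", "peoe_charges", "PEOE_PARAMS"]

#: (a, b, c) electronegativity coefficients, Gasteiger-Marsili 1980 set.
PEOE_PARAMS = {
    ("H", ""): (7.17, 6.24, -0.56),
    ("C", "sp3"): (7.98, 9.18, 1.88),
    ("C", "sp2"): (8.79, 9.32, 1.51),
    ("C", "sp"): (10.39, 9.45, 0.73),
    ("N", "sp3"): (11.54, 10.82, 1.36),
    ("N", "sp2"): (12.87, 11.15, 0.85),
    ("N", "sp"): (15.68, 11.70, -0.27),
    ("O", "sp3"): (14.18, 12.92, 1.39),
    ("O", "sp2"): (17.07, 13.79, 0.47),
    ("F", ""): (14.66, 13.85, 2.31),
    ("Cl", ""): (11.00, 9.69, 1.35),
    ("Br", ""): (10.08, 8.47, 1.16),
    ("I", ""): (9.90, 7.96, 0.96),
    ("S", "sp3"): (10.14, 9.13, 1.38),
}

H_CATION_CHI = 20.02


def _coeffs(element: str, hybrid: str):
    for key in ((element, hybrid), (element, ""), (element, "sp3")):
        if key in PEOE_PARAMS:
            return PEOE_PARAMS[key]
    raise ValueError(f"no PEOE electronegativity parameters for element "
                     f"{element!r} (hybridization {hybrid!r})")


def peoe_charges(elements: Sequence[str], bonds: Sequence[tuple],
                 hybridizations: Sequence[str] | None = None,
                 formal_charges: Sequence[float] | None = None,
                 iterations: int = 12) -> np.ndarray:
    """PEOE charges for a molecule given elements and a bond list.

    ``hybridizations`` gives the sigma framework tag per atom ("sp3",
    "sp2", "sp", or "" for one-state elements); defaults to sp3.  Formal
    charges seed the iteration, so the net charge of the result equals the
    net formal charge exactly (pairwise transfers conserve charge).
    """
    n = len(elements)
    if iterations < 6:
        raise ValueError("PEOE needs >= 6 iterations to converge")
    hyb = list(hybridizations) if hybridizations is not None else ["sp3"] * n
    abc = np.array([_coeffs(e, h) for e, h in zip(elements, hyb)])
    chi_plus = np.array([
        H_CATION_CHI if e == "H" else abc[i].sum()
        for i, e in enumerate(elements)])
    q = (np.array(formal_charges, float) if formal_charges is not None
         else np.zeros(n))
    for it in range(1, iterations + 1):
        damp = 0.5 ** it
        chi = abc[:, 0] + abc[:, 1] * q + abc[:, 2] * q * q
        dq = np.zeros(n)
        for i, j in bonds:
            if chi[i] == chi[j]:
                continue
            donor = i if chi[i] < chi[j] else j
            transfer = abs(chi[j] - chi[i]) / chi_plus[donor] * damp
            if donor == i:
                dq[i] += transfer
                dq[j] -= transfer
            else:
                dq[j] += transfer
                dq[i] -= transfer
        q = q + dq
    return q


def assign_gasteiger_charges(molecule, bonds: Sequence[tuple] | None = None,
                             hybridizations: Sequence[str] | None = None,
                             formal_charges: Sequence[float] | None = None,
                             iterations: int = 12) -> ChargeSet:
    """ChargeSet for a :class:`~synthonic.cell.Molecule` (or instance).

    Bond list defaults to the molecule's own bond graph.  The returned set
    is keyed by atom label, provenance ``"gasteiger"``.
    """
    if bonds is None:
        bonds = getattr(molecule, "bonds", None)
        if bonds is None:
            raise ValueError("molecule has no bond graph; pass bonds=")
    q = peoe_charges(molecule.elements, bonds, hybridizations,
                     formal_charges, iterations)
    return ChargeSet(dict(zip(molecule.labels, q.tolist())),
                     provenance="gasteiger")
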