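"""Physical constants, element isotope tables and amino-acid composition.

Monoisotopic masses are CODATA/IUPAC values; isotope abundances are the
IUPAC 2013 representative values.  Only C, H, N, O and S occur in the 20
standard residues, which is all the envelope simulator needs.
"""

from __future__ import annotations

# Masses in Da (unified atomic mass units)
PROTON_MASS = 1.007276466
H1_MASS = 1.0078250319
H2_MASS = 2.0141017780
#: mass gained when an amide H is replaced by D
DELTA_MASS_D = H2_MASS - H1_MASS  # 1.00627674 Da

WATER_MONO_MASS = 18.0105646863

# element -> list of (mass offset from lightest isotope in Da, abundance)
# Offsets are exact isotope-mass differences, not nominal integers.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(0.0, 0.9893), (13.0033548378 - 12.0, 0.0107)],
    "H": [(0.0, 0.999885), (H2_MASS - H1_MASS, 0.000115)],
    "N": [(0.0, 0.99636), (15.0001088989 - 14.0030740052, 0.00364)],
    "O": [
        (0.0, 0.99757),
        (16.9991315 - 15.9949146221, 0.00038),
        (17.9991604 - 15.9949146221, 0.00205),
    ],
    "S": [
        (0.0, 0.9499),
        (32.97145876 - 31.97207069, 0.0075),
        (33.96786690 - 31.97207069, 0.0425),
        (35.96708076 - 31.97207069, 0.0001),
    ],
}

MONO_MASS: dict[str, float] = {
    "C": 12.0,
    "H": H1_MASS,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
}

# Residue (not free amino acid) elemental composition: C, H, N, O, S.
RESIDUE_FORMULA: dict[str, dict[str, int]] = {
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
}

STANDARD_RESIDUES = frozenset(RESIDUE_FORMULA)


def peptide_formula(sequence: str) -> dict[str, int]:
    """Elemental composition of a peptide (residues + one water)."""
    formula = {"C": 0, "H": 2, "N": 0, "O": 1, "S": 0}
    for pos, aa in enumerate(sequence, start=1):
        try:
            res = RESIDUE_FORMULA[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} at position {pos}") from None
        for el, n in res.items():
            formula[el] += n
    return {el: n for el, n in formula.items() if n > 0}


def peptide_mono_mass(sequence: str) -> float:
    """Monoisotopic neutral mass of a peptide in Da."""
    return sum(MONO_MASS[el] * n for el, n in peptide_formula(sequence).items())
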