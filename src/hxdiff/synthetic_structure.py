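"""Synthetic stand-in crystal lattice for the ISB packing analysis.

The deposited Survivin-Borealin-INCENP crystal structure (PDB 2QFA) is not
bundled here and cannot be fetched in an offline environment, so this
module constructs a SYNTHETIC stand-in: an ISB-like heterotrimer (chains
A = Survivin-like, B = Borealin-like 10-109, C = INCENP-like 1-58) in an
orthorhombic P 21 21 21 cell, with coordinates arranged so that the crystal
packing reproduces the geometry reported for the real lattice — the
carboxylate of INCENP E42 sits 2.90 A from the NZ of a symmetry copy of
Borealin K37 (a genuine inter-trimer salt bridge), while E40 sits ~6.5 A
from the copy's K63 (too far to bond).  Only those stated facts are built
in; every contact is then *detected*, not asserted, by the lattice
pipeline.  All other coordinates are generic (chains laid out on spherical
spirals with charged side-chain atoms on outward normals).

The file is plain PDB text with CRYST1 and REMARK 290 records, generated
at run time.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .synthetic_sequences import default_isb_chains

CELL = (40.0, 50.0, 60.0)
SPACE_GROUP = "P 21 21 21"
# fractional operators of P 21 21 21
OPERATORS = (
    "X,Y,Z",
    "-X+1/2,-Y,Z+1/2",
    "-X,Y+1/2,-Z+1/2",
    "X+1/2,-Y+1/2,-Z",
)

_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "E": "GLU",
    "Q": "GLN", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: distance built into the stand-in for the E42-K37 inter-copy salt bridge
E42_K37_DISTANCE = 2.90
#: distance built in for the E40-K63 decoy (beyond salt-bridge range)
E40_K63_DISTANCE = 6.50


def _sphere_spiral(n: int, radius: float, center: np.ndarray) -> np.ndarray:
    """n points on a Fibonacci spiral over a sphere (CA placeholder trace)."""
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1) * radius
    return pts + center


def _side_chain_atoms(aa: str, ca: np.ndarray, outward: np.ndarray) -> list[tuple[str, np.ndarray]]:
    u = outward / np.linalg.norm(outward)
    # an arbitrary tangent for two-atom carboxylates / guanidinium spreads
    t = np.cross(u, [0.0, 0.0, 1.0])
    if np.linalg.norm(t) < 1e-6:
        t = np.cross(u, [0.0, 1.0, 0.0])
    t /= np.linalg.norm(t)
    if aa == "D":
        return [("CB", ca + 1.5 * u), ("CG", ca + 2.5 * u),
                ("OD1", ca + 3.1 * u + 0.55 * t), ("OD2", ca + 3.1 * u - 0.55 * t)]
    if aa == "E":
        return [("CB", ca + 1.5 * u), ("CG", ca + 2.5 * u), ("CD", ca + 3.6 * u),
                ("OE1", ca + 4.2 * u + 0.55 * t), ("OE2", ca + 4.2 * u - 0.55 * t)]
    if aa == "K":
        return [("CB", ca + 1.5 * u), ("CG", ca + 2.6 * u), ("CD", ca + 3.7 * u),
                ("CE", ca + 4.8 * u), ("NZ", ca + 5.9 * u)]
    if aa == "R":
        return [("CB", ca + 1.5 * u), ("CG", ca + 2.6 * u), ("CD", ca + 3.7 * u),
                ("NE", ca + 4.7 * u), ("CZ", ca + 5.3 * u),
                ("NH1", ca + 6.0 * u + 0.55 * t), ("NH2", ca + 6.0 * u - 0.55 * t)]
    return []


def _op2_image(p: np.ndarray) -> np.ndarray:
    """Cartesian image of a point under operator 2 plus translation (0,1,-1).

    Operator 2 of the cell is (x,y,z) -> (-x+a/2, -y, z+c/2); adding the
    lattice shift (0,+b,-c) keeps the image near the asymmetric unit, which
    is what creates the inter-trimer packing interface of this stand-in.
    """
    a, b, c = CELL
    return np.array([a / 2 - p[0], b - p[1], p[2] - c / 2])


def build_synthetic_lattice() -> list[tuple[str, int, str, str, np.ndarray]]:
    """Atom records: (chain, residue number, residue name, atom name, xyz)."""
    chains = {ch.chain_id: ch for ch in default_isb_chains()}
    layout = {
        # structure chain -> (construct chain, construct range, sphere center, radius)
        "A": ("Survivin", (1, 120), np.array([14.0, 14.0, 15.0]), 11.0),
        "B": ("Borealin", (10, 109), np.array([14.0, 33.0, 41.0]), 11.0),
        "C": ("INCENP", (1, 58), np.array([31.0, 22.0, 27.0]), 9.0),
    }
    atoms: list[tuple[str, int, str, str, np.ndarray]] = []
    positions: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}
    for sc, (construct, (lo, hi), center, radius) in layout.items():
        seq = chains[construct].subsequence(lo, hi)
        ca = _sphere_spiral(len(seq), radius, center)
        for i, aa in enumerate(seq):
            resid = lo + i
            outward = ca[i] - center
            positions[(sc, resid)] = (ca[i], outward)
            atoms.append((sc, resid, _THREE[aa], "CA", ca[i]))
            for name, xyz in _side_chain_atoms(aa, ca[i], outward):
                atoms.append((sc, resid, _THREE[aa], name, xyz))

    # engineer the packing interface from the stated geometry
    def charged_tip(chain: str, resid: int) -> np.ndarray:
        for c, r, _, name, xyz in atoms:
            if c == chain and r == resid and name in ("NZ", "OE1"):
                return xyz
        raise KeyError((chain, resid))

    def replace_residue(chain: str, resid: int, new_atoms: list[tuple[str, np.ndarray]]) -> None:
        nonlocal atoms
        resname = next(rn for c, r, rn, _, _ in atoms if c == chain and r == resid)
        atoms = [a for a in atoms if not (a[0] == chain and a[1] == resid)]
        atoms.extend((chain, resid, resname, name, xyz) for name, xyz in new_atoms)

    k37_image = _op2_image(charged_tip("B", 37))
    k63_image = _op2_image(charged_tip("B", 63))
    # direction from the INCENP-like blob toward the image point
    for resid, target, dist in ((42, k37_image, E42_K37_DISTANCE),
                                (40, k63_image, E40_K63_DISTANCE)):
        u = layout["C"][2] - target
        u /= np.linalg.norm(u)
        t = np.cross(u, [0.0, 0.0, 1.0])
        t /= np.linalg.norm(t)
        oe1 = target + dist * u
        replace_residue("C", resid, [
            ("CA", oe1 + 2.8 * u), ("CB", oe1 + 2.2 * u), ("CG", oe1 + 1.6 * u),
            ("CD", oe1 + 0.9 * u + 0.3 * t),
            ("OE1", oe1), ("OE2", oe1 + 0.6 * u + 1.0 * t),
        ])
    atoms.sort(key=lambda a: (a[0], a[1], a[3] != "CA", a[3]))
    return atoms


def write_synthetic_pdb(path: str | Path) -> Path:
    """Write the synthetic stand-in lattice as a PDB file with symmetry records."""
    from .lattice import parse_operator

    a, b, c = CELL
    lines = [
        "HEADER    SYNTHETIC STAND-IN FOR AN ISB-LIKE CRYSTAL LATTICE",
        "TITLE     SYNTHETIC ISB HETEROTRIMER PACKING MODEL (NOT PDB 2QFA)",
        "REMARK 290",
        "REMARK 290 CRYSTALLOGRAPHIC SYMMETRY TRANSFORMATIONS",
    ]
    for op_no, op in enumerate(OPERATORS, start=1):
        rot_f, trans_f = parse_operator(op)
        cellm = np.diag(CELL)
        rot = rot_f  # orthorhombic cell: fractional rotation == Cartesian
        trans = cellm @ trans_f
        for axis in range(3):
            lines.append(
                f"REMARK 290   SMTRY{axis + 1}  {op_no:2d}"
                f"{rot[axis, 0]:10.6f}{rot[axis, 1]:10.6f}{rot[axis, 2]:10.6f}"
                f"     {trans[axis]:10.5f}"
            )
    lines.append(
        f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} {SPACE_GROUP:<11s}{4:4d}"
    )
    serial = 1
    for chain, resid, resname, name, xyz in build_synthetic_lattice():
        element = name[0]
        lines.append(
            f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain}{resid:4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
        )
        serial += 1
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path
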