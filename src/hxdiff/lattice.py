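"""Crystal-lattice contact analysis.

Expands symmetry mates of an asymmetric unit (space-group operators plus
lattice translations), enumerates inter-copy residue contacts with a
KD-tree, classifies salt bridges (acidic side-chain oxygen to basic
side-chain nitrogen within a cutoff), and intersects the bridges with a
differential-HX consensus track to rank candidate interface residues.

Operators are taken, in order of precedence, from an explicit override,
from the file's REMARK 290 records, or from a small named-space-group
table.  All operator algebra is done in Cartesian coordinates derived from
the CRYST1 cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

ACIDIC_ATOMS = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
BASIC_ATOMS = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
HIS_ATOMS = {("HIS", "ND1"), ("HIS", "NE2")}

DEFAULT_SALT_BRIDGE_CUTOFF = 4.0  # Angstrom, charged-group heavy atoms

#: fractional operator strings for a few common space groups; real files
#: normally carry REMARK 290 and never consult this table
SPACE_GROUP_OPS: dict[str, tuple[str, ...]] = {
    "P 1": ("X,Y,Z",),
    "P 1 2 1": ("X,Y,Z", "-X,Y,-Z"),
    "P 1 21 1": ("X,Y,Z", "-X,Y+1/2,-Z"),
    "C 1 2 1": ("X,Y,Z", "-X,Y,-Z", "X+1/2,Y+1/2,Z", "-X+1/2,Y+1/2,-Z"),
    "P 2 2 2": ("X,Y,Z", "-X,-Y,Z", "-X,Y,-Z", "X,-Y,-Z"),
    "P 21 21 21": (
        "X,Y,Z",
        "-X+1/2,-Y,Z+1/2",
        "-X,Y+1/2,-Z+1/2",
        "X+1/2,-Y+1/2,-Z",
    ),
}


def parse_operator(op_string: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a fractional operator like ``-X+1/2,Y,Z+1/2`` into (R, t)."""
    rot = np.zeros((3, 3))
    trans = np.zeros(3)
    parts = op_string.upper().replace(" ", "").split(",")
    if len(parts) != 3:
        raise ValueError(f"operator {op_string!r} must have three components")
    axes = {"X": 0, "Y": 1, "Z": 2}
    for i, part in enumerate(parts):
        # tokenize into signed terms
        for sign, term in _signed_terms(part):
            if term in axes:
                rot[i, axes[term]] += sign
            else:
                if "/" in term:
                    num, den = term.split("/")
                    trans[i] += sign * float(num) / float(den)
                else:
                    trans[i] += sign * float(term)
    return rot, trans


def _signed_terms(expr: str):
    terms, sign, cur = [], 1.0, ""
    for ch in expr:
        if ch in "+-":
            if cur:
                terms.append((sign, cur))
                cur = ""
            sign = 1.0 if ch == "+" else -1.0
        else:
            cur += ch
    if cur:
        terms.append((sign, cur))
    return terms


@dataclass
class CrystalCell:
    box: np.ndarray  # rows are the a, b, c vectors in Cartesian Angstrom

    @property
    def matrix(self) -> np.ndarray:
        """Columns are the cell vectors: cartesian = matrix @ fractional."""
        return self.box.T

    def frac_op_to_cartesian(self, rot_f: np.ndarray, trans_f: np.ndarray):
        a = self.matrix
        return a @ rot_f @ np.linalg.inv(a), a @ trans_f


@dataclass
class Structure:
    atoms: struc.AtomArray
    cell: CrystalCell | None
    space_group: str | None
    remark290_ops: list[tuple[np.ndarray, np.ndarray]]  # Cartesian (R, t)


@dataclass
class LatticeCopy:
    """One symmetry mate: operator index, lattice translation, atoms."""

    copy_id: str
    op_index: int
    translation: tuple[int, int, int]
    atoms: struc.AtomArray


def read_structure(path: str, keep_hetero: bool = False) -> Structure:
    """Read a PDB file: polymer heavy atoms, cell, space group, operators.

    Alternate locations resolve to the highest-occupancy conformer; waters
    and (by default) other heteroatoms are excluded; hydrogens are dropped.
    """
    pdb_file = pdbio.PDBFile.read(path)
    atoms = pdb_file.get_structure(model=1, altloc="occupancy")
    mask = atoms.element != "H"
    mask &= atoms.res_name != "HOH"
    if not keep_hetero:
        mask &= ~atoms.hetero
    atoms = atoms[mask]
    cell = CrystalCell(np.asarray(atoms.box)) if atoms.box is not None else None
    try:
        space_group, _ = pdb_file.get_space_group()
    except Exception:
        space_group = None
    ops = _parse_remark290(pdb_file)
    return Structure(atoms, cell, space_group, ops)


def _parse_remark290(pdb_file: pdbio.PDBFile) -> list[tuple[np.ndarray, np.ndarray]]:
    lines = pdb_file.get_remark(290) or []
    rows: dict[int, list[tuple[int, np.ndarray, float]]] = {}
    for line in lines:
        fields = line.split()
        if len(fields) >= 6 and fields[0].startswith("SMTRY"):
            axis = int(fields[0][-1]) - 1  # SMTRY1/2/3 -> row index
            op_no = int(fields[1])
            r = np.array([float(fields[2]), float(fields[3]), float(fields[4])])
            t = float(fields[5])
            rows.setdefault(op_no, []).append((axis, r, t))
    ops = []
    for op_no in sorted(rows):
        rot = np.zeros((3, 3))
        trans = np.zeros(3)
        for axis, r, t in rows[op_no]:
            rot[axis] = r
            trans[axis] = t
        ops.append((rot, trans))
    return ops


def resolve_operators(
    structure: Structure,
    operator_override: Sequence[str] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cartesian space-group operators for a structure.

    Precedence: explicit fractional operator strings, then REMARK 290, then
    the internal table keyed by the CRYST1 space-group symbol.
    """
    if operator_override:
        if structure.cell is None:
            raise ValueError("operator override requires a CRYST1 cell")
        return [
            structure.cell.frac_op_to_cartesian(*parse_operator(s))
            for s in operator_override
        ]
    if structure.remark290_ops:
        return structure.remark290_ops
    sg = (structure.space_group or "").strip()
    if sg in SPACE_GROUP_OPS:
        if structure.cell is None:
            raise ValueError("space-group expansion requires a CRYST1 cell")
        return [
            structure.cell.frac_op_to_cartesian(*parse_operator(s))
            for s in SPACE_GROUP_OPS[sg]
        ]
    raise ValueError(
        f"cannot resolve symmetry operators: no REMARK 290 records and space group "
        f"{sg!r} is not in the internal table — supply operators explicitly "
        "(fractional strings such as '-X+1/2,-Y,Z+1/2')"
    )


def expand_lattice(
    structure: Structure,
    shell: int = 1,
    operator_override: Sequence[str] | None = None,
    prune_distance: float | None = None,
) -> list[LatticeCopy]:
    """All symmetry mates within ``shell`` unit cells of the asymmetric unit.

    The identity operator with zero translation (the asymmetric unit
    itself) is excluded.  With ``prune_distance`` set, copies whose bounding
    boxes are farther than that from the asymmetric unit's are dropped.
    """
    if shell < 1:
        raise ValueError("shell must be >= 1")
    if structure.cell is None:
        raise ValueError("lattice expansion requires a CRYST1 cell")
    ops = resolve_operators(structure, operator_override)
    coords = structure.atoms.coord
    cell_vectors = structure.cell.box  # rows a, b, c
    lo0, hi0 = coords.min(axis=0), coords.max(axis=0)
    copies = []
    rng_t = range(-shell, shell + 1)
    for op_index, (rot, trans) in enumerate(ops):
        base = coords @ rot.T + trans
        identity = np.allclose(rot, np.eye(3)) and np.allclose(trans, 0)
        for na in rng_t:
            for nb in rng_t:
                for nc in rng_t:
                    if identity and na == nb == nc == 0:
                        continue
                    shift = na * cell_vectors[0] + nb * cell_vectors[1] + nc * cell_vectors[2]
                    moved = base + shift
                    if prune_distance is not None:
                        lo, hi = moved.min(axis=0), moved.max(axis=0)
                        gap = np.maximum(lo - hi0, lo0 - hi)
                        if np.any(gap > prune_distance):
                            continue
                    mate = structure.atoms.copy()
                    mate.coord = moved
                    copies.append(
                        LatticeCopy(
                            copy_id=f"op{op_index}_t{na}{nb}{nc}",
                            op_index=op_index,
                            translation=(na, nb, nc),
                            atoms=mate,
                        )
                    )
    return copies


_CONTACT_COLUMNS = [
    "chain_a", "res_a", "resname_a", "atom_a",
    "chain_b", "res_b", "resname_b", "atom_b",
    "distance", "copy_id", "op_index", "translation",
]


def find_contacts(
    asu: struc.AtomArray,
    copies: Sequence[LatticeCopy],
    cutoff: float = 4.0,
) -> pd.DataFrame:
    """Atom-level contacts between the asymmetric unit and lattice copies.

    Returns every heavy-atom pair within ``cutoff``; KD-tree indexed so the
    scan is near-linear in atom count.  Aggregate with
    :func:`residue_contact_summary` for per-residue-pair minima.
    """
    if not 0 < cutoff <= 10.0:
        raise ValueError("cutoff must be in (0, 10] Angstrom")
    if not copies:
        raise ValueError("empty lattice-copy list")
    asu_coord = asu.coord.astype(np.float64)
    tree = cKDTree(asu_coord)
    rows = []
    for copy in copies:
        copy_coord = copy.atoms.coord.astype(np.float64)
        pairs = tree.query_ball_point(copy_coord, r=cutoff)
        for j, neighbors in enumerate(pairs):
            if not neighbors:
                continue
            for i in neighbors:
                d = float(np.linalg.norm(asu_coord[i] - copy_coord[j]))
                rows.append(
                    (
                        asu.chain_id[i], int(asu.res_id[i]), asu.res_name[i], asu.atom_name[i],
                        copy.atoms.chain_id[j], int(copy.atoms.res_id[j]),
                        copy.atoms.res_name[j], copy.atoms.atom_name[j],
                        d, copy.copy_id, copy.op_index, copy.translation,
                    )
                )
    return pd.DataFrame(rows, columns=_CONTACT_COLUMNS)


def residue_contact_summary(contacts: pd.DataFrame) -> pd.DataFrame:
    """Minimum inter-atomic distance per residue pair and partner copy."""
    if contacts.empty:
        return contacts.copy()
    keys = ["chain_a", "res_a", "resname_a", "chain_b", "res_b", "resname_b", "copy_id"]
    idx = contacts.groupby(keys, sort=False)["distance"].idxmin()
    return contacts.loc[idx].sort_values("distance").reset_index(drop=True)


def classify_salt_bridges(
    contacts: pd.DataFrame,
    cutoff: float = DEFAULT_SALT_BRIDGE_CUTOFF,
    include_histidine: bool = False,
) -> pd.DataFrame:
    """Salt bridges among atom-level contacts.

    Keeps acidic side-chain oxygen to basic side-chain nitrogen pairs
    within ``cutoff`` and reports the minimal qualifying distance per
    residue pair (columns oriented acidic -> basic regardless of which side
    of the contact the acid sat on).  Histidine is excluded by default
    because its protonation state in a crystal is ambiguous.
    """
    basic = BASIC_ATOMS | (HIS_ATOMS if include_histidine else set())
    rows = []
    for tup in contacts.itertuples(index=False):
        a_key = (tup.resname_a, tup.atom_a)
        b_key = (tup.resname_b, tup.atom_b)
        if a_key in ACIDIC_ATOMS and b_key in basic:
            acid = (tup.chain_a, tup.res_a, tup.resname_a, tup.atom_a)
            base = (tup.chain_b, tup.res_b, tup.resname_b, tup.atom_b)
        elif b_key in ACIDIC_ATOMS and a_key in basic:
            acid = (tup.chain_b, tup.res_b, tup.resname_b, tup.atom_b)
            base = (tup.chain_a, tup.res_a, tup.resname_a, tup.atom_a)
        else:
            continue
        if tup.distance > cutoff:
            continue
        rows.append((*acid, *base, tup.distance, tup.copy_id, tup.op_index, tup.translation))
    cols = [
        "acid_chain", "acid_res", "acid_resname", "acid_atom",
        "base_chain", "base_res", "base_resname", "base_atom",
        "distance", "copy_id", "op_index", "translation",
    ]
    df = pd.DataFrame(rows, columns=cols)
    if df.empty:
        return df
    keys = ["acid_chain", "acid_res", "base_chain", "base_res", "copy_id"]
    idx = df.groupby(keys, sort=False)["distance"].idxmin()
    out = df.loc[idx].sort_values("distance").reset_index(drop=True)
    out["distance_report"] = out["distance"].round(1)
    return out


def intersect_with_track(
    salt_bridges: pd.DataFrame,
    track: pd.DataFrame,
    chain_mapping: Mapping[str, tuple[str, int]],
    protection_threshold: float = -5.0,
) -> pd.DataFrame:
    """Annotate salt bridges with consensus protection and rank them.

    ``chain_mapping``: structure chain -> (construct chain, offset), with
    construct residue = structure residue + offset.  Bridges whose both
    residues are protected below ``protection_threshold`` rank first; ties
    break on distance.  Residues on unmapped chains or without HX coverage
    are flagged, never dropped.
    """
    lookup: dict[tuple[str, int], float] = {}
    covered: dict[tuple[str, int], bool] = {}
    for _, row in track.iterrows():
        key = (row["chain"], int(row["residue"]))
        covered[key] = bool(row["covered"])
        if row["covered"]:
            lookup[key] = float(row["mean_delta"])

    def annotate(chain: str, res: int) -> tuple[float, str]:
        if chain not in chain_mapping:
            return np.nan, "unmapped_chain"
        ckey = (chain_mapping[chain][0], res + chain_mapping[chain][1])
        if ckey not in covered:
            return np.nan, "outside_construct"
        if not covered[ckey]:
            return np.nan, "uncovered"
        return lookup[ckey], "ok"

    out = salt_bridges.copy()
    acid_vals = [annotate(c, r) for c, r in zip(out["acid_chain"], out["acid_res"])]
    base_vals = [annotate(c, r) for c, r in zip(out["base_chain"], out["base_res"])]
    out["acid_mean_delta"] = [v for v, _ in acid_vals]
    out["acid_flag"] = [f for _, f in acid_vals]
    out["base_mean_delta"] = [v for v, _ in base_vals]
    out["base_flag"] = [f for _, f in base_vals]
    out["both_protected"] = (
        (out["acid_mean_delta"] <= protection_threshold)
        & (out["base_mean_delta"] <= protection_threshold)
    ).fillna(False)
    out = out.sort_values(
        ["both_protected", "distance"], ascending=[False, True]
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
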