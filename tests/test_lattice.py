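"""Crystal-lattice expansion, contact search and salt-bridge classification."""

import numpy as np
import pandas as pd
import pytest

import biotite.structure as struc

from hxdiff.lattice import (
    CrystalCell,
    LatticeCopy,
    Structure,
    classify_salt_bridges,
    expand_lattice,
    find_contacts,
    intersect_with_track,
    parse_operator,
    read_structure,
    residue_contact_summary,
    resolve_operators,
)


def _atom_array(records):
    """records: (chain, res_id, res_name, atom_name, element, xyz)."""
    arr = struc.AtomArray(len(records))
    for i, (ch, rid, rname, aname, el, xyz) in enumerate(records):
        arr.chain_id[i] = ch
        arr.res_id[i] = rid
        arr.res_name[i] = rname
        arr.atom_name[i] = aname
        arr.element[i] = el
        arr.coord[i] = xyz
    return arr


def _p1_structure(atoms, cell=(10.0, 20.0, 30.0)):
    return Structure(
        atoms=atoms,
        cell=CrystalCell(np.diag(cell)),
        space_group="P 1",
        remark290_ops=[],
    )


class TestOperators:
    def test_parse_identity_and_screw(self):
        r, t = parse_operator("X,Y,Z")
        np.testing.assert_array_equal(r, np.eye(3))
        np.testing.assert_array_equal(t, 0)
        r, t = parse_operator("-X+1/2,-Y,Z+1/2")
        np.testing.assert_array_equal(r, np.diag([-1, -1, 1]))
        np.testing.assert_allclose(t, [0.5, 0, 0.5])

    def test_apply_then_invert_returns_original(self):
        cell = CrystalCell(np.diag([10.0, 20.0, 30.0]))
        rot, trans = cell.frac_op_to_cartesian(*parse_operator("-X+1/2,Y+1/2,-Z"))
        x = np.array([1.234, -5.1, 7.7])
        y = rot @ x + trans
        back = np.linalg.solve(rot, y - trans)
        np.testing.assert_allclose(back, x, atol=1e-6)

    def test_unresolvable_space_group_names_remedy(self):
        s = _p1_structure(_atom_array([("A", 1, "GLY", "CA", "C", (1, 1, 1))]))
        s.space_group = "P 63 2 2"
        with pytest.raises(ValueError, match="explicitly"):
            resolve_operators(s)


class TestExpandLattice:
    def test_p1_shell1_gives_26_copies(self):
        s = _p1_structure(_atom_array([("A", 1, "GLY", "CA", "C", (1, 2, 3))]))
        copies = expand_lattice(s, shell=1)
        assert len(copies) == 26
        ids = {c.copy_id for c in copies}
        assert len(ids) == 26 and "op0_t000" not in ids

    def test_screw_operator_matches_hand_computed_fractional_arithmetic(self):
        # orthorhombic 10x20x30 cell, single atom at (1, 2, 3):
        # fractional (0.1, 0.1, 0.1); op (-x+1/2, -y, z+1/2) -> frac
        # (0.4, -0.1, 0.6) -> Cartesian (4, -2, 18)
        s = _p1_structure(_atom_array([("A", 1, "GLY", "CA", "C", (1.0, 2.0, 3.0))]))
        copies = expand_lattice(s, shell=1, operator_override=["X,Y,Z", "-X+1/2,-Y,Z+1/2"])
        target = next(c for c in copies if c.op_index == 1 and c.translation == (0, 0, 0))
        np.testing.assert_allclose(target.atoms.coord[0], [4.0, -2.0, 18.0], atol=1e-6)

    def test_shell_validation(self):
        s = _p1_structure(_atom_array([("A", 1, "GLY", "CA", "C", (1, 2, 3))]))
        with pytest.raises(ValueError):
            expand_lattice(s, shell=0)


class TestFindContacts:
    def _two_atom_world(self, d):
        asu = _atom_array([("A", 1, "GLY", "CA", "C", (0.0, 0.0, 0.0))])
        partner = _atom_array([("A", 1, "GLY", "CA", "C", (d, 0.0, 0.0))])
        copy = LatticeCopy("op0_t100", 0, (1, 0, 0), partner)
        return asu, [copy]

    def test_contact_within_cutoff(self):
        asu, copies = self._two_atom_world(3.0)
        contacts = find_contacts(asu, copies, cutoff=4.0)
        assert len(contacts) == 1
        assert contacts["distance"].iloc[0] == pytest.approx(3.0)

    def test_no_contact_beyond_cutoff(self):
        asu, copies = self._two_atom_world(3.0)
        assert find_contacts(asu, copies, cutoff=2.5).empty

    def test_empty_copy_list_rejected(self):
        asu, _ = self._two_atom_world(3.0)
        with pytest.raises(ValueError, match="empty"):
            find_contacts(asu, [], cutoff=4.0)

    def test_matches_bruteforce_allpairs_on_toy_lattice(self):
        rng = np.random.default_rng(5)
        n = 300
        records = [
            ("A", i // 4 + 1, "GLY", "CA", "C", rng.uniform(0, 12, 3)) for i in range(n)
        ]
        asu = _atom_array(records)
        s = _p1_structure(asu, cell=(12.0, 12.0, 12.0))
        copies = expand_lattice(s, shell=1)
        contacts = find_contacts(asu, copies, cutoff=4.0)
        got = {
            (r.chain_a, r.res_a, r.atom_a, r.copy_id, r.res_b, r.atom_b,
             round(r.distance, 4))
            for r in contacts.itertuples(index=False)
        }
        expected = set()
        for copy in copies:
            for i in range(n):
                d = np.linalg.norm(
                    asu.coord[i].astype(np.float64) - copy.atoms.coord.astype(np.float64),
                    axis=1,
                )
                for j in np.where(d <= 4.0)[0]:
                    expected.add(
                        (asu.chain_id[i], int(asu.res_id[i]), asu.atom_name[i],
                         copy.copy_id, int(copy.atoms.res_id[j]),
                         copy.atoms.atom_name[j], round(float(d[j]), 4))
                    )
        assert got == expected

    def test_rigid_motion_invariance(self):
        """Rotating the asymmetric unit together with its cell leaves all
        contact distances unchanged."""
        rng = np.random.default_rng(3)
        records = [("A", i + 1, "GLY", "CA", "C", rng.uniform(0, 10, 3)) for i in range(40)]
        asu = _atom_array(records)
        s = _p1_structure(asu, cell=(10.0, 10.0, 10.0))
        d0 = find_contacts(asu, expand_lattice(s, shell=1), 4.0)["distance"].sort_values()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        asu2 = asu.copy()
        asu2.coord = asu.coord @ rot.T + np.array([5.0, -3.0, 2.0])
        s2 = Structure(asu2, CrystalCell(np.diag([10.0, 10.0, 10.0]) @ rot.T),
                       "P 1", [])
        d1 = find_contacts(asu2, expand_lattice(s2, shell=1), 4.0)["distance"].sort_values()
        np.testing.assert_allclose(d0.to_numpy(), d1.to_numpy(), atol=1e-6)


def _contact_row(resname_a, atom_a, resname_b, atom_b, distance):
    return {
        "chain_a": "C", "res_a": 42, "resname_a": resname_a, "atom_a": atom_a,
        "chain_b": "B", "res_b": 37, "resname_b": resname_b, "atom_b": atom_b,
        "distance": distance, "copy_id": "op1_t000", "op_index": 1,
        "translation": (0, 0, 0),
    }


class TestClassifySaltBridges:
    def test_glu_lys_pair_within_cutoff(self):
        contacts = pd.DataFrame([_contact_row("GLU", "OE1", "LYS", "NZ", 2.9)])
        out = classify_salt_bridges(contacts)
        assert len(out) == 1
        assert out["distance"].iloc[0] == pytest.approx(2.9)
        assert out["distance_report"].iloc[0] == 2.9

    def test_beyond_cutoff_excluded(self):
        contacts = pd.DataFrame([_contact_row("GLU", "OE1", "LYS", "NZ", 5.5)])
        assert classify_salt_bridges(contacts, cutoff=4.0).empty

    def test_nonacidic_atom_excluded(self):
        contacts = pd.DataFrame([_contact_row("ALA", "CB", "LYS", "NZ", 2.9)])
        assert classify_salt_bridges(contacts).empty

    def test_orientation_normalized(self):
        # basic side listed first: output still reads acid -> base
        row = _contact_row("LYS", "NZ", "GLU", "OE2", 3.1)
        out = classify_salt_bridges(pd.DataFrame([row]))
        assert out["acid_resname"].iloc[0] == "GLU"
        assert out["base_resname"].iloc[0] == "LYS"

    def test_histidine_optional(self):
        contacts = pd.DataFrame([_contact_row("GLU", "OE1", "HIS", "NE2", 3.0)])
        assert classify_salt_bridges(contacts).empty
        assert len(classify_salt_bridges(contacts, include_histidine=True)) == 1

    def test_minimum_distance_per_residue_pair(self):
        contacts = pd.DataFrame([
            _contact_row("GLU", "OE1", "LYS", "NZ", 3.4),
            _contact_row("GLU", "OE2", "LYS", "NZ", 2.8),
        ])
        out = classify_salt_bridges(contacts)
        assert len(out) == 1
        assert out["distance"].iloc[0] == pytest.approx(2.8)


class TestIntersectWithTrack:
    def _bridges(self):
        rows = [
            dict(acid_chain="C", acid_res=42, acid_resname="GLU", acid_atom="OE1",
                 base_chain="B", base_res=37, base_resname="LYS", base_atom="NZ",
                 distance=2.9, copy_id="op1", op_index=1, translation=(0, 0, 0),
                 distance_report=2.9),
            dict(acid_chain="C", acid_res=10, acid_resname="ASP", acid_atom="OD1",
                 base_chain="B", base_res=5, base_resname="ARG", base_atom="NH1",
                 distance=2.5, copy_id="op1", op_index=1, translation=(0, 0, 0),
                 distance_report=2.5),
        ]
        return pd.DataFrame(rows)

    def _track(self, deltas):
        rows = []
        for (chain, res), d in deltas.items():
            rows.append((chain, res, d, 1, d is not None))
        return pd.DataFrame(rows, columns=["chain", "residue", "mean_delta", "n_peptides", "covered"])

    def test_doubly_protected_bridge_ranks_first(self):
        track = self._track({("INCENP", 42): -15.0, ("Borealin", 37): -15.0,
                             ("INCENP", 10): 0.0, ("Borealin", 5): -20.0})
        mapping = {"C": ("INCENP", 0), "B": ("Borealin", 0)}
        out = intersect_with_track(self._bridges(), track, mapping)
        assert out.iloc[0]["acid_res"] == 42 and bool(out.iloc[0]["both_protected"])
        # exhaustive re-ranking oracle: all both-protected before others,
        # distance ascending within each block
        blocks = out.groupby("both_protected", sort=False)
        order = list(out["both_protected"])
        assert order == sorted(order, reverse=True)
        for _, blk in blocks:
            assert list(blk["distance"]) == sorted(blk["distance"])

    def test_empty_track_flags_all_orders_by_distance(self):
        track = self._track({})
        out = intersect_with_track(self._bridges(), track, {"C": ("INCENP", 0), "B": ("Borealin", 0)})
        assert (out["acid_flag"] != "ok").all()
        assert list(out["distance"]) == sorted(out["distance"])

    def test_unmapped_chain_flagged_not_dropped(self):
        track = self._track({("INCENP", 42): -15.0})
        out = intersect_with_track(self._bridges(), track, {"C": ("INCENP", 0)})
        assert len(out) == 2
        assert (out["base_flag"] == "unmapped_chain").all()


class TestSyntheticLatticeDetection:
    def test_reciprocal_contacts_detected(self, tmp_path):
        """A contact from the ASU to a copy implies the reciprocal contact
        under the inverse operator, at the same distance."""
        from hxdiff.synthetic_structure import write_synthetic_pdb

        path = write_synthetic_pdb(tmp_path / "synthetic_lattice.pdb")
        s = read_structure(str(path))
        copies = expand_lattice(s, shell=1)
        bridges = classify_salt_bridges(find_contacts(s.atoms, copies, 4.0))
        key = bridges.set_index(["acid_chain", "acid_res", "base_chain", "base_res"])
        pair = key.loc[("C", 42, "B", 37)]
        assert len(pair) == 2  # the bridge and its reciprocal image
        assert pair["distance"].nunique() == 1 or np.allclose(
            pair["distance"].iloc[0], pair["distance"].iloc[1], atol=1e-4
        )
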