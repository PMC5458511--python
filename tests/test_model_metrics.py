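import gemmi
import numpy as np
import pytest

from volscape.model_metrics import (
    FULL,
    POLY_ALA,
    REMOVED,
    apply_truncation,
    read_model,
    ring_hexagon_angles,
    segment_bfactor_classify,
    write_model,
)

# atoms per residue used by the synthetic chains below
_RES_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "GLY": ["N", "CA", "C", "O"],
    "LEU": ["N", "CA", "C", "O", "CB", "CG", "CD1", "CD2"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
}


def make_structure(chain_specs):
    """Synthetic model: chain_specs maps chain name -> list of (resname, b)."""
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for cname, residues in chain_specs.items():
        chain = gemmi.Chain(cname)
        for i, (resname, b) in enumerate(residues, start=1):
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(i, " ")
            for j, aname in enumerate(_RES_ATOMS[resname]):
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(aname[0])
                atom.pos = gemmi.Position(i * 3.8, j * 0.5, 0.0)
                atom.b_iso = b
                atom.occ = 1.0
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


class TestSegmentClassification:
    @pytest.mark.parametrize(
        "b, expected",
        [(50.0, FULL), (130.0, POLY_ALA), (200.0, REMOVED), (110.0, POLY_ALA), (150.0, POLY_ALA), (150.01, REMOVED)],
    )
    def test_threshold_rules(self, b, expected):
        st = make_structure({"A": [("LEU", b)] * 5})
        report = segment_bfactor_classify(st)
        assert len(report.segments) == 1
        assert report.segments[0].klass == expected

    def test_three_segment_chain(self):
        st = make_structure({"A": [("LEU", 50.0)] * 5 + [("LEU", 130.0)] * 5 + [("LEU", 200.0)] * 5})
        report = segment_bfactor_classify(st)
        assert [s.klass for s in report.segments] == [FULL, POLY_ALA, REMOVED]
        assert [(s.start, s.end) for s in report.segments] == [(1, 5), (6, 10), (11, 15)]

    def test_trailing_short_segment_classified_alone(self):
        st = make_structure({"A": [("SER", 50.0)] * 7})
        report = segment_bfactor_classify(st)
        assert [s.n_residues for s in report.segments] == [5, 2]

    def test_mean_over_atoms_not_residues(self):
        # unequal atom counts: mean must weight every atom equally
        residues = [("GLY", 100.0)] * 2 + [("LEU", 130.0)] * 3
        st = make_structure({"A": residues})
        report = segment_bfactor_classify(st)
        expected = np.mean([100.0] * 8 + [130.0] * 24)
        assert report.segments[0].mean_b == pytest.approx(expected)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError):
            segment_bfactor_classify(gemmi.Structure())


class TestTruncation:
    def test_full_report_leaves_model_unchanged(self):
        st = make_structure({"A": [("LEU", 50.0)] * 5})
        report = segment_bfactor_classify(st)
        out = apply_truncation(st, report)
        assert sum(len(r) for r in out[0]["A"]) == 5 * len(_RES_ATOMS["LEU"])

    def test_all_removed_empties_model(self):
        st = make_structure({"A": [("LEU", 200.0)] * 5})
        report = segment_bfactor_classify(st)
        out = apply_truncation(st, report)
        assert sum(len(ch) for ch in out[0]) == 0

    def test_mixed_chain_atom_counts_match_hand_count(self):
        st = make_structure({"A": [("LEU", 50.0)] * 5 + [("SER", 130.0)] * 5 + [("LEU", 200.0)] * 5})
        report = segment_bfactor_classify(st)
        out = apply_truncation(st, report)
        chain = out[0]["A"]
        # full LEU x5 = 40 atoms; SER poly-ala keeps N,CA,C,O,CB = 25; removed = 0
        assert sum(len(r) for r in chain) == 5 * 8 + 5 * 5
        assert [r.name for r in chain] == ["LEU"] * 5 + ["ALA"] * 5

    def test_glycine_keeps_no_cb(self):
        st = make_structure({"A": [("GLY", 130.0)] * 5})
        report = segment_bfactor_classify(st)
        out = apply_truncation(st, report)
        for res in out[0]["A"]:
            assert [a.name for a in res] == ["N", "CA", "C", "O"]
            assert res.name == "ALA"

    def test_truncation_idempotent_partition(self):
        st = make_structure({"A": [("LEU", 50.0)] * 5 + [("SER", 130.0)] * 5})
        report = segment_bfactor_classify(st)
        out = apply_truncation(st, report)
        report2 = segment_bfactor_classify(out)
        # poly-ala segments lose side-chain atoms, so their mean B may change,
        # but the surviving segment boundaries must be stable
        assert [(s.start, s.end) for s in report2.segments] == [
            (s.start, s.end) for s in report.segments
        ]
        assert report2.segments[0].klass == FULL


def _hexagon(radius=10.0, z=0.0):
    ang = np.deg2rad(np.arange(0, 360, 60))
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(6, z)])


def make_ring_structure(points):
    st = gemmi.Structure()
    model = gemmi.Model("1")
    for i, p in enumerate(points):
        chain = gemmi.Chain(chr(ord("A") + i))
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(100, " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.pos = gemmi.Position(*p)
        atom.b_iso = 30.0
        res.add_atom(atom)
        chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


def _selections():
    return [(chr(ord("A") + i), 100, "CA") for i in range(6)]


class TestRingAngles:
    def test_regular_hexagon_all_120(self):
        st = make_ring_structure(_hexagon())
        report = ring_hexagon_angles(st, _selections())
        np.testing.assert_allclose(report.inner_angles, 120.0, atol=1e-6)
        assert report.max_deviation == pytest.approx(0.0, abs=1e-6)

    def test_angle_sum_720_for_convex_ring(self, rng):
        pts = _hexagon()
        pts[:, :2] += rng.normal(scale=0.8, size=(6, 2))  # still convex
        report = ring_hexagon_angles(make_ring_structure(pts), _selections())
        assert report.angle_sum == pytest.approx(720.0, abs=1e-6)

    def test_pulled_vertex_matches_planar_trigonometry(self):
        pts = _hexagon()
        pts[0, :2] *= 0.5  # pull one vertex towards the center
        report = ring_hexagon_angles(make_ring_structure(pts), _selections())

        def inner(a, b, c):
            e1, e2 = a - b, c - b
            cosv = e1 @ e2 / np.linalg.norm(e1) / np.linalg.norm(e2)
            return np.degrees(np.arccos(np.clip(cosv, -1, 1)))

        expected = [
            inner(pts[(i - 1) % 6, :2], pts[i, :2], pts[(i + 1) % 6, :2]) for i in range(6)
        ]
        np.testing.assert_allclose(report.inner_angles, expected, atol=1e-6)

    def test_invariant_under_rigid_motion(self, rng):
        from scipy.spatial.transform import Rotation

        pts = _hexagon()
        pts[2, :2] *= 0.7
        base = ring_hexagon_angles(make_ring_structure(pts), _selections())
        R = Rotation.random(rng=rng).as_matrix()
        moved = pts @ R.T + np.array([11.0, -5.0, 40.0])
        got = ring_hexagon_angles(make_ring_structure(moved), _selections())
        np.testing.assert_allclose(got.inner_angles, base.inner_angles, atol=1e-6)

    def test_missing_atom_named_in_error(self):
        st = make_ring_structure(_hexagon())
        sels = _selections()
        sels[3] = ("D", 999, "CA")
        with pytest.raises(KeyError, match="999"):
            ring_hexagon_angles(st, sels)

    def test_collinear_ring_rejected(self):
        pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        with pytest.raises(ValueError, match="degenerate|collinear"):
            ring_hexagon_angles(make_ring_structure(pts), _selections())


class TestModelIO:
    def test_pdb_round_trip_preserves_bfactors(self, tmp_path):
        st = make_structure({"A": [("LEU", 87.5)] * 5})
        path = tmp_path / "model.pdb"
        write_model(st, path)
        back = read_model(path)
        bvals = [a.b_iso for r in back[0]["A"] for a in r]
        np.testing.assert_allclose(bvals, 87.5, atol=0.01)
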