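"""SASA, interface footprints, Kabsch superposition, ternary models, Matthews."""

import math

import numpy as np
import pytest

from dutafab import (
    CrystalForm,
    StructureError,
    build_ternary_model,
    detect_clashes,
    interface_footprint,
    kabsch_superpose,
    matthews,
    read_structure,
    sasa,
    solvent_content,
    write_pdb,
)
from dutafab.fixtures import make_cobinding_pair, make_toy_complex
from dutafab.structure_tools import (
    DEFAULT_PROBE,
    Structure,
    cell_volume,
    from_atoms,
    matthews_coefficient,
)


def _atoms(*rows):
    return from_atoms(list(rows))


def _single(x=0.0, y=0.0, z=0.0, el="C", chain="A", res=1):
    return (chain, res, "", "TOY", f"{el}1", el, x, y, z)


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = _atoms(_single())
        r = 1.70 + DEFAULT_PROBE
        res = sasa(s)
        assert res.total == pytest.approx(4 * math.pi * r * r, rel=1e-12)

    def test_two_sphere_analytic_cap(self):
        """Equal spheres at distance d: buried cap height is R - d/2 each."""
        d = 2.0
        s = _atoms(_single(0, 0, 0), _single(d, 0, 0, res=2))
        R = 1.70 + DEFAULT_PROBE
        exposed_each = 4 * math.pi * R * R - 2 * math.pi * R * (R - d / 2)
        res = sasa(s, n_points=10000)
        assert res.total == pytest.approx(2 * exposed_each, rel=0.01)
        assert res.per_atom[0] == pytest.approx(exposed_each, rel=0.01)

    def test_distant_atoms_additive(self):
        far = 2 * (1.8 + DEFAULT_PROBE) + 1.0
        s = _atoms(_single(), _single(far, 0, 0, el="S", res=2))
        iso_c = 4 * math.pi * (1.70 + DEFAULT_PROBE) ** 2
        iso_s = 4 * math.pi * (1.80 + DEFAULT_PROBE) ** 2
        assert sasa(s).total == pytest.approx(iso_c + iso_s, rel=1e-12)

    def test_point_count_convergence(self):
        s, _ = make_toy_complex(3, "contacting")
        coarse = sasa(s, n_points=960).total
        dense = sasa(s, n_points=10000).total
        assert abs(coarse - dense) / dense < 0.02

    def test_rigid_invariance(self):
        s, _ = make_toy_complex(7, "contacting")
        base = sasa(s).total
        theta = 0.7
        rot = np.array([[math.cos(theta), -math.sin(theta), 0],
                        [math.sin(theta), math.cos(theta), 0],
                        [0, 0, 1.0]])
        moved = s.transformed(rot, np.array([11.0, -3.0, 5.0]))
        assert abs(sasa(moved).total - base) / base < 1e-3

    def test_matches_independent_reference_implementation(self):
        biotite_struct = pytest.importorskip("biotite.structure")
        s, _ = make_toy_complex(9, "contacting", n_atoms=(30, 30))
        arr = biotite_struct.AtomArray(len(s))
        arr.coord = s.coords.astype(np.float32)
        arr.chain_id = np.array(s.chain_ids)
        arr.res_id = np.array(s.res_seq)
        arr.res_name = np.array(s.res_names)
        arr.atom_name = np.array(s.atom_names)
        arr.element = np.array(s.elements)
        ref = float(biotite_struct.sasa(arr, probe_radius=DEFAULT_PROBE,
                                        point_number=1000,
                                        vdw_radii="Single").sum())
        mine = sasa(s, n_points=1000).total
        assert abs(mine - ref) / ref < 0.01

    def test_unknown_element_rejected(self):
        s = _atoms(("A", 1, "", "TOY", "Q1", "Q", 0.0, 0.0, 0.0))
        with pytest.raises(StructureError, match="unknown element"):
            sasa(s)


class TestFootprint:
    def test_separated_groups_zero_buried(self):
        s, _ = make_toy_complex(5, "separated")
        fp = interface_footprint(s, ["A"], ["B"], n_points=240)
        assert fp.side_a_buried == 0.0 and fp.side_b_buried == 0.0
        assert fp.contact_residues_a == () and fp.contact_residues_b == ()

    def test_contacting_matches_dense_oracle(self):
        s, exp = make_toy_complex(5, "contacting")
        fp = interface_footprint(s, ["A"], ["B"])
        assert fp.side_a_buried == pytest.approx(exp["buried_a_dense"], rel=0.01)
        assert fp.side_b_buried == pytest.approx(exp["buried_b_dense"], rel=0.01)

    def test_per_residue_decomposition_sums_to_total(self):
        s, _ = make_toy_complex(6, "contacting")
        fp = interface_footprint(s, ["A"], ["B"])
        assert sum(fp.per_residue_a.values()) == pytest.approx(fp.side_a_buried)
        assert all(v >= 0 for v in fp.per_residue_a.values())
        assert set(fp.contact_residues_a) <= {
            r for r, v in fp.per_residue_a.items() if v > 0}

    def test_both_zero_iff_contact_free(self):
        for seed in range(4):
            s, exp = make_toy_complex(seed, "separated")
            fp = interface_footprint(s, ["A"], ["B"], n_points=240)
            assert (fp.side_a_buried, fp.side_b_buried) == (0.0, 0.0)
        s, _ = make_toy_complex(2, "contacting")
        fp = interface_footprint(s, ["A"], ["B"], n_points=240)
        assert fp.side_a_buried > 0 and fp.side_b_buried > 0

    def test_overlapping_groups_rejected(self):
        s, _ = make_toy_complex(1, "separated")
        with pytest.raises(StructureError, match="overlap"):
            interface_footprint(s, ["A"], ["A"])

    def test_cdr_attribution_on_labelled_antibody(self, template_nfv):
        """Residues numbered like HCDR3 vs framework split the buried area."""
        from dutafab.fv_numbering import annotate_regions

        ann = annotate_regions(template_nfv, "kabat")
        # antibody chain "H": residue 98 (HCDR3) touching, residue 10 (HFR1) far
        s = _atoms(
            ("H", 98, "", "TOY", "C1", "C", 0.0, 0.0, 0.0),
            ("H", 10, "", "TOY", "C1", "C", 0.0, 30.0, 0.0),
            ("V", 1, "", "TOY", "C1", "C", 2.5, 0.0, 0.0),
        )
        fp = interface_footprint(s, ["H"], ["V"], annotation=ann,
                                 antibody_chain_map={"H": "H"})
        assert set(fp.cdr_attribution) == {"HCDR3"}
        assert fp.cdr_attribution["HCDR3"] == pytest.approx(fp.side_a_buried)


class TestKabsch:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(20, 3))
        sup = kabsch_superpose(pts, pts)
        assert sup.rmsd < 1e-12
        assert np.allclose(sup.rotation, np.eye(3), atol=1e-12)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(100, 3))
        from scipy.spatial.transform import Rotation

        r0 = Rotation.random(random_state=7).as_matrix()
        t0 = np.array([4.0, -2.0, 9.0])
        sup = kabsch_superpose(pts, pts @ r0.T + t0)
        assert np.abs(sup.rotation - r0).max() < 1e-9
        assert sup.rmsd < 1e-9
        assert np.abs(sup.translation - t0).max() < 1e-9

    def test_proper_rotation_always(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a, b = rng.normal(size=(2, 8, 3))
            sup = kabsch_superpose(a, b)
            assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(sup.rotation.T @ sup.rotation, np.eye(3), atol=1e-9)

    def test_noise_rmsd_scales_as_sigma_sqrt3(self):
        rng = np.random.default_rng(5)
        sigma = 0.1
        pts = rng.normal(scale=5.0, size=(500, 3))
        ref = pts + rng.normal(scale=sigma, size=pts.shape)
        sup = kabsch_superpose(pts, ref)
        assert sup.rmsd == pytest.approx(sigma * math.sqrt(3), rel=0.10)

    def test_beats_random_rotations_on_small_instances(self):
        """Optimality check against a 10^4-rotation brute-force oracle."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        rand_rots = Rotation.random(10_000, random_state=9).as_matrix()
        for n in (4, 5, 6):
            a = rng.normal(size=(n, 3))
            b = rng.normal(size=(n, 3))
            best = kabsch_superpose(a, b).rmsd
            ac = a - a.mean(axis=0)
            bc = b - b.mean(axis=0)
            brute = np.sqrt(
                ((ac @ rand_rots.transpose(0, 2, 1) - bc) ** 2)
                .sum(axis=(1, 2)) / n
            ).min()
            assert best <= brute + 1e-12

    def test_degenerate_collinear_rejected(self):
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(StructureError, match="degenerate"):
            kabsch_superpose(line, line + 1.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(StructureError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestClashesAndTernary:
    def test_engineered_clash_count_exact(self):
        s, exp = make_toy_complex(13, "clashing", n_clashes=7)
        clashes = detect_clashes(s.select_chains(["A"]), s.select_chains(["B"]))
        assert len(clashes) == exp["n_clashes"] == 7
        for c in clashes:
            assert c.overlap == pytest.approx(0.6, abs=1e-9)

    def test_clash_count_rigid_invariant(self):
        s, _ = make_toy_complex(13, "clashing", n_clashes=4)
        theta = 1.1
        rot = np.array([[math.cos(theta), 0, math.sin(theta)],
                        [0, 1.0, 0],
                        [-math.sin(theta), 0, math.cos(theta)]])
        moved = s.transformed(rot, np.array([-7.0, 2.0, 13.0]))
        a, b = moved.select_chains(["A"]), moved.select_chains(["B"])
        assert len(detect_clashes(a, b)) == 4

    def test_self_superposition_overlays_antigen(self):
        c1, _, _ = make_cobinding_pair(17)
        model = build_ternary_model(c1, c1, ["F"])
        assert model.superposition.rmsd < 1e-9
        ag = c1.select_chains(["G"])
        transplanted = model.model.select_chains(["xG"])
        assert np.allclose(transplanted.coords, ag.coords, atol=1e-9)
        # every transplanted atom clashes with its own original
        assert len(model.clashes) >= len(ag)

    def test_opposite_face_antigens_cobind_without_clashes(self):
        c1, c2, exp = make_cobinding_pair(19, opposite=True)
        model = build_ternary_model(c1, c2, ["F"])
        assert model.superposition.rmsd < 1e-6
        assert len(model.clashes) == exp["expected_clashes"] == 0
        # oracle: explicit pairwise distance scan with vdW radii
        ag1 = model.model.select_chains(["G"])
        ag2 = model.model.select_chains(["xG"])
        d = np.linalg.norm(ag1.coords[:, None] - ag2.coords[None], axis=2)
        assert (d > (ag1.radii()[:, None] + ag2.radii()[None]) - 0.4).all()

    def test_same_face_antigens_clash(self):
        c1, c2, _ = make_cobinding_pair(23, opposite=False)
        model = build_ternary_model(c1, c2, ["F"])
        assert len(model.clashes) > 0

    def test_too_few_mapped_atoms_rejected(self):
        c1, c2, _ = make_cobinding_pair(29, n_fab=20)
        with pytest.raises(StructureError, match="too few mapped"):
            build_ternary_model(c1, c2, ["F"], min_mapped=50)


class TestStructureIO:
    def test_three_atom_roundtrip(self, tmp_path):
        s = _atoms(_single(1.234, 5.678, -9.012),
                   _single(0.001, 0.002, 0.003, el="N", res=2),
                   _single(-3.1, 2.2, 1.1, el="O", res=3))
        path = tmp_path / "toy.pdb"
        write_pdb(s, path)
        back = read_structure(path)
        assert len(back) == 3
        assert np.allclose(back.coords, s.coords, atol=1e-3)
        assert back.elements == s.elements

    def test_altloc_highest_occupancy_kept(self, tmp_path):
        lines = [
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40 10.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60 10.00           C",
            "END",
        ]
        path = tmp_path / "altloc.pdb"
        path.write_text("\n".join(lines) + "\n")
        s = read_structure(path)
        assert len(s) == 1
        assert s.coords[0][0] == pytest.approx(5.0)

    def test_pdb_and_mmcif_renderings_identical(self, tmp_path):
        import gemmi

        s = _atoms(_single(1.0, 2.0, 3.0), _single(4.0, 5.0, 6.0, el="S", res=2))
        pdb_path = tmp_path / "x.pdb"
        write_pdb(s, pdb_path)
        st = gemmi.read_structure(str(pdb_path))
        st.setup_entities()
        cif_path = tmp_path / "x.cif"
        st.make_mmcif_document().write_file(str(cif_path))
        a = read_structure(pdb_path)
        b = read_structure(cif_path)
        assert a.elements == b.elements and a.res_seq == b.res_seq
        assert np.allclose(a.coords, b.coords, atol=1e-3)

    def test_waters_stripped_by_default(self, tmp_path):
        lines = [
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C",
            "HETATM    2  O   HOH A 101       9.000   0.000   0.000  1.00 10.00           O",
            "END",
        ]
        path = tmp_path / "wat.pdb"
        path.write_text("\n".join(lines) + "\n")
        assert len(read_structure(path)) == 1
        assert len(read_structure(path, strip_waters=False)) == 2


class TestMatthews:
    def test_published_solvent_content_values(self):
        # crystal-form bookkeeping reported for the two deposited complexes
        assert 100 * solvent_content(2.18) == pytest.approx(43.5, abs=0.3)
        assert 100 * solvent_content(2.63) == pytest.approx(53.2, abs=0.3)

    def test_zero_solvent_limit(self):
        vbar = 0.74
        assert solvent_content(1.66054 * vbar, vbar) == 0.0

    def test_crystal_form_pipeline(self):
        v = cell_volume(60.0, 70.0, 80.0, 90.0, 90.0, 90.0)
        assert v == pytest.approx(60 * 70 * 80)
        cf = CrystalForm(cell_volume=v, copies=2, z=4, mw=30_000.0)
        vm, s = matthews(cf)
        assert vm == pytest.approx(v / (4 * 2 * 30_000.0))
        assert s == pytest.approx(1 - 1.66054 * 0.74 / vm)
        assert matthews_coefficient(cf) == vm

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(StructureError):
            CrystalForm(cell_volume=-1.0, copies=2, z=4, mw=75_000.0)
        with pytest.raises(StructureError):
            solvent_content(0.0)
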