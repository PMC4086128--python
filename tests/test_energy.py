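"""Pair potentials, restraint construction, and the hybrid energy."""

import numpy as np
import pytest

from sitedock.energy import (HybridEnergy, PairPotentialTable, Restraint,
                             RestraintSet, build_restraints, residue_score,
                             restraint_energy)
from sitedock.fixtures import FixtureSpec, build_target
from sitedock.structio import Atom, Residue


@pytest.fixture(scope="module")
def table():
    return PairPotentialTable.default()


class TestPairEnergy:
    def test_clash_is_capped_at_one(self, table):
        assert table.pair_energy("C", "C", 0, 0, 0.3) == pytest.approx(1.0)

    def test_minimum_is_negative_and_uncapped(self, table):
        r_min, e_min = table.pair_minimum("C", "C")
        assert e_min < 0
        assert table.pair_energy("C", "C", 0, 0, r_min) \
            == pytest.approx(e_min, abs=1e-9)
        assert 3.5 < r_min < 4.5  # near the combined vdW radius

    def test_cap_on_dense_grid_every_type_pair(self, table):
        """Max over r in [0.1, 12] (step 0.01) is <= 1.0 for every pair,
        and equals 1.0 at clashing distances."""
        grid = np.arange(0.1, 12.0, 0.01)
        for ti in table.types:
            for tj in table.types:
                e = table.pair_energy(ti, tj, 0.2, -0.2, grid)
                assert e.max() <= 1.0 + 1e-12
                assert e[0] == pytest.approx(1.0)  # deep clash hits the cap

    def test_tail_monotone_to_zero(self, table):
        e8 = float(table.pair_energy("C", "C", 0, 0, 8.0))
        e12 = float(table.pair_energy("C", "C", 0, 0, 12.0))
        assert abs(e12) < abs(e8)
        grid = np.arange(6.0, 12.0, 0.01)
        e = np.asarray(table.pair_energy("C", "C", 0, 0, grid))
        assert np.all(np.diff(np.abs(e)) <= 1e-12)

    def test_hbond_pair_deeper_than_vdw(self, table):
        _, e_hb = table.pair_minimum("O", "O")
        _, e_cc = table.pair_minimum("C", "C")
        assert e_hb < e_cc  # 12-10 well is deeper

    def test_nonpositive_distance_raises(self, table):
        with pytest.raises(ValueError):
            table.pair_energy("C", "C", 0, 0, 0.0)


def _res(aa, ca, centroid, index=1):
    atoms = [Atom("CA", "C", np.asarray(ca, dtype=float))]
    if centroid is not None:
        atoms.append(Atom("CB", "C", np.asarray(centroid, dtype=float)))
    return Residue(index=index, aa_type=aa, atoms=atoms)


class TestResidueScore:
    def test_identical_orientation_scores_one(self):
        a = _res("LEU", [0, 0, 0], [1, 1, 0])
        b = _res("LEU", [5, 5, 5], [6, 6, 5])
        assert residue_score(a, b, 0.0) == pytest.approx(1.0)

    def test_perpendicular_orientations_score_zero(self):
        a = _res("LEU", [0, 0, 0], [1, 0, 0])
        b = _res("LEU", [0, 0, 0], [0, 1, 0])
        assert residue_score(a, b, 0.0) == pytest.approx(0.0)

    def test_antiparallel_clamped_to_zero(self):
        a = _res("LEU", [0, 0, 0], [1, 0, 0])
        b = _res("LEU", [0, 0, 0], [-1, 0, 0])
        assert residue_score(a, b, 0.0) == 0.0

    def test_type_mismatch_scores_zero(self):
        a = _res("LEU", [0, 0, 0], [1, 0, 0])
        b = _res("VAL", [0, 0, 0], [1, 0, 0])
        assert residue_score(a, b, 0.0) == 0.0

    def test_deviation_gate_at_2A(self):
        a = _res("LEU", [0, 0, 0], [1, 0, 0])
        b = _res("LEU", [0, 0, 0], [1, 0, 0])
        assert residue_score(a, b, 2.0) == pytest.approx(1.0)
        assert residue_score(a, b, 2.0001) == 0.0
        assert residue_score(a, b, 3.0) == 0.0

    def test_glycine_fallback(self):
        a = _res("GLY", [0, 0, 0], None)
        b = _res("GLY", [0, 0, 0], None)
        assert residue_score(a, b, 0.5) == 1.0

    def test_frame_rotation_applied_to_template(self):
        from scipy.spatial.transform import Rotation
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        a = _res("LEU", [0, 0, 0], [1, 0, 0])
        # template vector is +y in its own frame; R maps it onto +x
        b = _res("LEU", [0, 0, 0], [0, -1, 0])
        assert residue_score(a, b, 0.0, rotation=R) == pytest.approx(1.0)
        assert residue_score(a, b, 0.0) == pytest.approx(0.0)


def _single_restraint_set(w, r_ref, d, anchor=(0.0, 0.0, 0.0)):
    rs = RestraintSet(
        restraints=[Restraint(ligand_atom_i=0, protein_atom_j=0,
                              template_k=0, r_ref=r_ref, d=d, weight=w)],
        protein_coords=np.array([anchor]))
    return rs


class TestRestraintEnergy:
    def test_satisfied_unit_weight_is_zero(self):
        rs = _single_restraint_set(1.0, 3.0, 0.5)
        assert restraint_energy(np.array([[3.0, 0, 0]]), rs) \
            == pytest.approx(0.0, abs=1e-12)

    def test_half_weight_closed_form(self):
        rs = _single_restraint_set(0.5, 3.0, 0.5)
        assert restraint_energy(np.array([[3.0, 0, 0]]), rs) \
            == pytest.approx(np.log(2.0), abs=1e-12)

    def test_matches_naive_double_loop_oracle(self):
        """3 ligand atoms x 4 protein atoms x 2 templates, random data."""
        rng = np.random.default_rng(12)
        p_coords = rng.uniform(-5, 5, (4, 3))
        restraints = []
        for i in range(3):
            for j in range(4):
                for k in range(2):
                    restraints.append(Restraint(
                        ligand_atom_i=i, protein_atom_j=j, template_k=k,
                        r_ref=float(rng.uniform(2, 6)),
                        d=float(rng.uniform(0.5, 2.0)),
                        weight=float(rng.uniform(0.05, 1.0))))
        rs = RestraintSet(restraints=restraints, protein_coords=p_coords)
        lig = rng.uniform(-5, 5, (3, 3))

        oracle = 0.0
        for i in range(3):
            inner = 0.0
            for r in restraints:
                if r.ligand_atom_i != i:
                    continue
                rij = np.linalg.norm(lig[i] - p_coords[r.protein_atom_j])
                inner += r.weight * np.exp(-(rij - r.r_ref) ** 2 / r.d ** 2)
            oracle += -np.log(inner)
        assert restraint_energy(lig, rs) == pytest.approx(oracle, abs=1e-10)

    def test_minimum_exactly_at_r_ref_by_scan(self):
        rs = _single_restraint_set(0.8, 3.0, 1.0)
        rr = np.arange(1.0, 6.0, 0.001)
        e = np.array([restraint_energy(np.array([[r, 0, 0]]), rs)
                      for r in rr])
        assert rr[np.argmin(e)] == pytest.approx(3.0, abs=0.002)

    def test_larger_d_flatter_gradient(self):
        """|dE/dr| at a fixed 0.5 A offset decreases with d."""
        slopes = []
        for d in (0.5, 1.0, 2.0, 4.0):
            rs = _single_restraint_set(1.0, 3.0, d)
            e1 = restraint_energy(np.array([[3.5, 0, 0]]), rs)
            e2 = restraint_energy(np.array([[3.51, 0, 0]]), rs)
            slopes.append(abs(e2 - e1) / 0.01)
        assert all(a > b for a, b in zip(slopes, slopes[1:]))

    def test_unrestrained_atom_excluded_finite(self):
        rs = _single_restraint_set(1.0, 3.0, 0.5)
        # atom 1 has no restraints; energy stays finite and ignores it
        lig = np.array([[3.0, 0, 0], [500.0, 0, 0]])
        assert np.isfinite(restraint_energy(lig, rs))
        assert restraint_energy(lig, rs) == pytest.approx(0.0, abs=1e-12)

    def test_far_pose_floored_not_divergent(self):
        rs = _single_restraint_set(1.0, 3.0, 0.5)
        e = restraint_energy(np.array([[300.0, 0, 0]]), rs)
        assert e == pytest.approx(-np.log(1e-12))


class TestBuildRestraints:
    def test_self_template_weights(self, clean_templates, table):
        """Template identical to the target: TM-score and residue scores
        are 1, so each weight equals its pair-energy optimality ratio."""
        target, tpls, truth = clean_templates
        from sitedock.ligandselect import select_ligands
        cand = select_ligands(tpls)[0]
        rs = build_restraints(cand, target, table)
        assert len(rs) > 0
        tpl = cand.supporting_templates[0]
        topo, lig = tpl.ligands[0]
        p_coords, p_types, p_charges, _ = target.heavy_atom_table()
        for r in rs.restraints:
            ti = topo.atoms[r.ligand_atom_i].autodock_type
            qi = topo.atoms[r.ligand_atom_i].partial_charge
            tj, qj = p_types[r.protein_atom_j], p_charges[r.protein_atom_j]
            _, e_min = table.pair_minimum(ti, tj, qi, qj)
            e_ref = float(table.pair_energy(ti, tj, qi, qj, r.r_ref))
            expected = float(np.clip(e_ref / e_min, 0.0, 1.0))
            assert r.weight == pytest.approx(expected, rel=1e-4)
            assert 0.0 <= r.weight <= 1.0
            assert r.d == pytest.approx(0.5)  # d_jk = 0 floored at 0.5 A

    def test_clashing_template_distance_weight_zero(self, table):
        """A restraint whose template distance is repulsive (uncapped
        energy > 0) gets clamped weight 0, i.e. is dropped."""
        r_clash = 2.0  # C-C at 2.0 A: strongly positive
        e = float(table.pair_energy("C", "C", 0, 0, r_clash, capped=False))
        assert e > 0
        _, e_min = table.pair_minimum("C", "C")
        assert np.clip(e / e_min, 0.0, 1.0) == 0.0

    def test_displaced_residue_generates_no_restraints(self, tmp_path, table):
        """d_jk = 3 A on a residue zeroes all restraints through it."""
        from sitedock.cli import load_templates
        from sitedock.fixtures import make_system
        from sitedock.ligandselect import select_ligands
        from sitedock.structio import read_protein
        d = tmp_path / "disp"
        make_system(FixtureSpec(template_noise=0.0, n_templates=1, seed=5), d)
        target = read_protein(d / "target.pdb")
        tpls = load_templates(target, d / "templates", d / "alignments",
                              d / "scores.tsv")
        cand = select_ligands(tpls)[0]
        rs0 = build_restraints(cand, target, table)
        touched = {r.protein_atom_j for r in rs0.restraints}
        _, _, _, p_res = target.heavy_atom_table()
        touched_res = {int(p_res[j]) for j in touched}
        # displace one contact residue in the *target* by 3 A: its d_jk
        # exceeds the 2 A gate and its restraints must vanish
        ri = sorted(touched_res)[0]
        for a in target.residues[ri].atoms:
            a.coords = a.coords + np.array([0.0, 0.0, 3.0])
        # recompute superposition against the modified target
        tpls2 = load_templates(target, d / "templates", d / "alignments",
                               d / "scores.tsv")
        cand2 = select_ligands(tpls2)[0]
        rs2 = build_restraints(cand2, target, table)
        res2 = {int(p_res[r.protein_atom_j]) for r in rs2.restraints}
        assert ri not in res2
        # restore (session-scoped target untouched: different instance)


class TestHybridEnergy:
    def test_empty_restraints_pure_physical(self, small_target, triatomic):
        hyb = HybridEnergy(small_target, triatomic, None)
        lig = triatomic.coords + np.array([30.0, 0.0, 10.0])
        assert hyb(lig) == pytest.approx(hyb.autodock_energy(lig))
        assert hyb.restraint_energy(lig) == 0.0

    def test_weight_arithmetic(self):
        # E_AD = -5.0, E_R = 2.0 -> total -2.8 with weight 1.1
        assert -5.0 + 1.1 * 2.0 == pytest.approx(-2.8)

    def test_hybrid_weight_recovered_from_components(
            self, clean_templates, table, triatomic):
        target, tpls, truth = clean_templates
        from sitedock.ligandselect import select_ligands
        cand = select_ligands(tpls)[0]
        rs = build_restraints(cand, target, table)
        topo = cand.poses[0][0]
        hyb = HybridEnergy(target, topo, rs, table)
        rng = np.random.default_rng(8)
        for _ in range(5):
            lig = np.array(truth["planted_coords"]) + rng.normal(0, 1.0, 3)
            e_r = hyb.restraint_energy(lig)
            if abs(e_r) < 1e-9:
                continue
            ratio = (hyb(lig) - hyb.autodock_energy(lig)) / e_r
            assert ratio == pytest.approx(1.1, abs=1e-9)

    def test_decomposition_reproduces_total(self, clean_templates, table):
        target, tpls, truth = clean_templates
        from sitedock.ligandselect import select_ligands
        cand = select_ligands(tpls)[0]
        rs = build_restraints(cand, target, table)
        topo = cand.poses[0][0]
        hyb = HybridEnergy(target, topo, rs, table)
        lig = np.array(truth["planted_coords"])
        total = hyb(lig)
        assert total == pytest.approx(
            hyb.autodock_energy(lig) + 1.1 * hyb.restraint_energy(lig),
            abs=1e-12)

    def test_rigid_motion_covariance(self, clean_templates, table):
        """Rigidly moving protein + restraint anchors + pose together
        leaves every energy term unchanged."""
        from scipy.spatial.transform import Rotation
        import copy
        target, tpls, truth = clean_templates
        from sitedock.ligandselect import select_ligands
        cand = select_ligands(tpls)[0]
        rs = build_restraints(cand, target, table)
        topo = cand.poses[0][0]
        hyb = HybridEnergy(target, topo, rs, table)
        lig = np.array(truth["planted_coords"])
        e0_ad, e0_r = hyb.autodock_energy(lig), hyb.restraint_energy(lig)

        R = Rotation.from_euler("xyz", [17, -42, 95], degrees=True).as_matrix()
        t = np.array([11.0, -3.0, 8.0])
        moved_target = copy.deepcopy(target)
        for res in moved_target.residues:
            for a in res.atoms:
                a.coords = a.coords @ R.T + t
        rs_moved = RestraintSet(restraints=rs.restraints,
                                protein_coords=rs.protein_coords @ R.T + t)
        hyb2 = HybridEnergy(moved_target, topo, rs_moved, table)
        lig2 = lig @ R.T + t
        assert hyb2.autodock_energy(lig2) == pytest.approx(e0_ad, abs=1e-9)
        assert hyb2.restraint_energy(lig2) == pytest.approx(e0_r, abs=1e-9)
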