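import math

import numpy as np
import pytest

from rdcsas._geometry import rotation_x, rotation_y, rotation_z
from rdcsas.conformer_metrics import (GAS_CONSTANT_KCAL, ShiftPuckerMap,
                                      StackingCriterion, bend_category,
                                      classify_pucker, compute_torsions,
                                      cooperativity, detect_coaxial,
                                      detect_extra_helical, detect_stacking,
                                      ensemble_distance, interhelical_euler,
                                      pucker_population, shift_to_c2endo,
                                      superpose_rmsd)
from rdcsas.structures import Atom, Conformer, HelixSpec, Residue, build_aform_helix
from rdcsas.synthetic_data import JunctionModel, generate_library


def _rigid(conf, seed=0):
    rng = np.random.default_rng(seed)
    R = rotation_z(rng.uniform(0, 360)) @ rotation_y(rng.uniform(0, 180)) \
        @ rotation_x(rng.uniform(0, 360))
    return conf.transformed(R, rng.normal(size=3) * 10)


class TestTorsions:
    def test_cis_and_trans_planar_quads(self):
        from rdcsas._geometry import dihedral
        p0, p1, p2 = np.array([1.0, 1.0, 0]), np.array([0.0, 0, 0]), np.array([1.5, 0, 0])
        cis = np.array([2.5, 1.0, 0.0])
        trans = np.array([2.5, -1.0, 0.0])
        assert dihedral(p0, p1, p2, cis) == pytest.approx(0.0, abs=1e-9)
        assert abs(dihedral(p0, p1, p2, trans)) == pytest.approx(180.0, abs=1e-9)

    def test_c3endo_template_phase_in_north_window(self, helix):
        tors = compute_torsions(helix)
        for res in helix.residues:
            assert 0.0 <= tors.residue(res.index)["P"] < 36.0

    def test_rigid_motion_leaves_all_torsions_unchanged(self, helix):
        t0 = compute_torsions(helix)
        t1 = compute_torsions(_rigid(helix, seed=4))
        for idx in t0.angles:
            for name, val in t0.angles[idx].items():
                other = t1.angles[idx][name]
                if math.isnan(val):
                    assert math.isnan(other)
                else:
                    diff = abs(val - other) % 360.0
                    assert min(diff, 360.0 - diff) < 1e-6

    def test_missing_atoms_reported_not_fatal(self, helix):
        import copy
        broken = copy.deepcopy(helix)
        res = broken.residues[0]
        res.atoms = [a for a in res.atoms if a.name != "C2'"]
        tors = compute_torsions(broken)
        assert res.index in tors.incomplete
        assert math.isnan(tors.residue(res.index)["P"])


class TestPucker:
    def test_canonical_phase_windows(self):
        from rdcsas.conformer_metrics import TorsionSet
        t = TorsionSet({1: {"P": 18.0, "nu_max": 38.0},
                        2: {"P": 162.0, "nu_max": 38.0},
                        3: {"P": 100.0, "nu_max": 5.0}})
        assert classify_pucker(t, 1).state == "C3'-endo"
        assert classify_pucker(t, 2).state == "C2'-endo"
        assert classify_pucker(t, 3).state == "ambiguous"

    def test_population_arithmetic_and_permutation_invariance(self):
        from rdcsas.structures import _pair_frame_nucleotide, _residue_from_template

        def nt(p):
            tpl = _pair_frame_nucleotide("U", +1, pucker_p=p)
            return Conformer([_residue_from_template(tpl, "U", 1, "A")])

        members = [nt(18.0)] * 17 + [nt(162.0)] * 3
        assert pucker_population(members, 1) == pytest.approx(0.15)
        assert pucker_population(members[::-1], 1) == pytest.approx(0.15)

    def test_all_c3endo_gives_zero(self, helix):
        assert pucker_population([helix], 18) == 0.0


class TestShiftMap:
    def test_anchor_endpoints(self):
        assert shift_to_c2endo(86.0) == 100.0
        assert shift_to_c2endo(94.0) == 0.0

    def test_midpoint_and_affinity(self):
        assert shift_to_c2endo(90.0) == 50.0
        # affine between anchors: equal steps give equal increments
        vals = [shift_to_c2endo(s, ShiftPuckerMap(clamp=False))
                for s in np.linspace(86, 94, 9)]
        np.testing.assert_allclose(np.diff(vals), -12.5)

    def test_clamping_outside_anchors(self):
        assert shift_to_c2endo(85.0) == 100.0
        assert shift_to_c2endo(95.0) == 0.0
        assert shift_to_c2endo(85.0, ShiftPuckerMap(clamp=False)) > 100.0


class TestInterhelicalEuler:
    def test_continuous_helix_has_no_bend(self):
        spec = HelixSpec("GCAGAG", "CUCUGC", tuple(range(1, 7)),
                         tuple(range(11, 17)))
        helix6 = build_aform_helix(spec)
        orient = interhelical_euler(helix6, ((4, 5, 6), (11, 12, 13)),
                                    ((1, 2, 3), (14, 15, 16)))
        assert orient.beta_h < 1e-3

    def test_constructed_bend_recovered(self):
        model = JunctionModel(bend_modes=[(60.0, 0.0, 1.0)], twist_sd=0.0, seed=9)
        lib = generate_library(model, 3)
        upper, lower = model.euler_ranges()
        for conf in lib:
            orient = interhelical_euler(conf, upper, lower)
            assert abs(orient.beta_h - 60.0) < 0.1

    def test_global_rotation_invariance(self):
        model = JunctionModel(seed=21)
        lib = generate_library(model, 2)
        upper, lower = model.euler_ranges()
        for conf in lib:
            a = interhelical_euler(conf, upper, lower)
            b = interhelical_euler(_rigid(conf, seed=8), upper, lower)
            assert abs(a.alpha_h - b.alpha_h) < 1e-3
            assert abs(a.beta_h - b.beta_h) < 1e-3
            assert abs(a.gamma_h - b.gamma_h) < 1e-3

    def test_recomposition_matches_relative_rotation(self):
        model = JunctionModel(seed=13)
        lib = generate_library(model, 5)
        upper, lower = model.euler_ranges()
        from rdcsas._geometry import compose_zyz
        for conf in lib:
            o = interhelical_euler(conf, upper, lower)
            R1 = compose_zyz(-o.alpha_h, o.beta_h, -o.gamma_h)
            np.testing.assert_allclose(o.rotation, R1, atol=1e-12)

    @pytest.mark.parametrize("beta,expected", [
        (30.0, "linear"), (45.0, "linear"), (60.0, "intermediate"),
        (70.0, "intermediate"), (90.0, "kinked")])
    def test_bend_categories(self, beta, expected):
        from rdcsas.conformer_metrics import InterhelicalOrientation
        o = InterhelicalOrientation(alpha_h=0.0, beta_h=beta, gamma_h=0.0)
        assert bend_category(o) == expected


class TestStacking:
    def test_sequential_helix_bases_stacked(self, helix):
        for a, b in ((18, 19), (19, 20), (20, 21), (41, 42), (42, 43)):
            assert detect_stacking(helix, a, b) is True

    def test_distant_bases_not_stacked(self, helix):
        assert detect_stacking(helix, 18, 21) is False

    def test_paired_coplanar_bases_not_stacked(self, helix):
        for a, b in ((18, 44), (19, 43), (20, 42)):
            assert detect_stacking(helix, a, b) is False

    def test_incomplete_ring_undetermined(self, helix):
        import copy
        broken = copy.deepcopy(helix)
        res = broken.residue(18)
        res.atoms = [a for a in res.atoms if a.name != "N7"]
        assert detect_stacking(broken, 18, 19) is None

    def test_thresholds_configurable(self, helix):
        strict = StackingCriterion(max_centroid_distance=1.0)
        assert detect_stacking(helix, 18, 19, strict) is False


class TestCoaxialAndFlips:
    def test_coaxial_junction_detected(self):
        model = JunctionModel(bend_modes=[(0.0, 0.0, 1.0)], twist_sd=0.0,
                              flip_prob=1.0, seed=2)
        lib = generate_library(model, 3)
        for conf in lib:
            assert detect_coaxial(conf, model.bridging_pairs()) is True

    def test_kinked_junction_not_coaxial(self):
        model = JunctionModel(bend_modes=[(90.0, 0.0, 1.0)], twist_sd=0.0,
                              flip_prob=1.0, seed=2)
        lib = generate_library(model, 3)
        for conf in lib:
            assert detect_coaxial(conf, model.bridging_pairs()) is False

    def test_empty_bridging_list_rejected(self, helix):
        with pytest.raises(ValueError):
            detect_coaxial(helix, [])

    def test_flipped_out_residues_called_extra_helical(self):
        model = JunctionModel(bend_modes=[(0.0, 0.0, 1.0)], twist_sd=0.0,
                              flip_prob=1.0, seed=6)
        lib = generate_library(model, 3)
        flank = model.flanking_bp_residues()
        for conf in lib:
            for r in model.numbering()["bulge"]:
                assert detect_extra_helical(conf, r, flank) is True

    def test_junction_proximal_stacked_residues_called_in(self):
        model = JunctionModel(bend_modes=[(0.0, 0.0, 1.0)], twist_sd=0.0,
                              flip_prob=0.0, seed=6)
        lib = generate_library(model, 2)
        flank = model.flanking_bp_residues()
        first, *_, last = model.numbering()["bulge"]
        for conf in lib:
            assert detect_extra_helical(conf, first, flank) is False
            assert detect_extra_helical(conf, last, flank) is False

    def test_flags_invariant_under_rigid_motion(self):
        model = JunctionModel(seed=30)
        conf = generate_library(model, 1)[0]
        moved = _rigid(conf, seed=31)
        flank = model.flanking_bp_residues()
        for r in model.numbering()["bulge"]:
            assert (detect_extra_helical(conf, r, flank)
                    == detect_extra_helical(moved, r, flank))
        assert (detect_coaxial(conf, model.bridging_pairs())
                == detect_coaxial(moved, model.bridging_pairs()))


class TestCooperativity:
    def test_factorized_table_gives_zero(self):
        rows = []
        for a in (0, 1):
            for b in (0, 1):
                for c in (0, 1):
                    rows += [[a, b, c]] * (4 if c else 12)
        res = cooperativity(np.array(rows, dtype=bool))
        assert abs(res.delta_g) < 1e-6

    def test_hand_constructed_table(self):
        rows = ([[0, 0, 0]] * 12 + [[1, 0, 0]] * 4 + [[0, 1, 0]] * 3
                + [[0, 0, 1]] * 3 + [[1, 1, 0]] * 4 + [[1, 0, 1]] * 4
                + [[1, 1, 1]] * 20)
        res = cooperativity(np.array(rows, dtype=bool))
        assert res.p_out == pytest.approx({0: 0.25, 1: 0.2, 2: 0.2})
        assert res.p_independent == pytest.approx(0.01)
        assert res.p_observed == pytest.approx(0.4)
        expected = -GAS_CONSTANT_KCAL * 298.0 * math.log(40.0)
        assert res.delta_g == pytest.approx(expected, abs=1e-9)
        assert res.delta_g == pytest.approx(-2.18, abs=0.01)

    def test_observed_fraction_eight_of_twenty(self):
        rows = [[1, 1, 1]] * 8 + [[0, 0, 0]] * 6 + [[1, 0, 0]] * 3 \
            + [[0, 1, 0]] * 2 + [[0, 0, 1]] * 1
        res = cooperativity(np.array(rows, dtype=bool))
        assert res.p_observed == pytest.approx(8 / 20)

    def test_zero_denominator_diagnosed(self):
        rows = [[1, 1, 1]] * 5
        with pytest.raises(ZeroDivisionError):
            cooperativity(np.array(rows, dtype=bool))


class TestSuperposeAndDistance:
    def test_identical_coordinates_zero(self, helix):
        assert superpose_rmsd(helix, helix) == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_zero(self, helix):
        assert superpose_rmsd(_rigid(helix, seed=3), helix) == pytest.approx(0.0, abs=1e-6)

    def test_matches_quaternion_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(30, 3)) * 5
        b = a + rng.normal(size=(30, 3)) * 0.8

        def conf(x):
            return Conformer([Residue(i + 1, "A", "A", [Atom("C1'", "C", p)])
                              for i, p in enumerate(x)])

        # Horn's closed-form quaternion superposition as the oracle
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        M = ac.T @ bc
        Sxx, Sxy, Sxz = M[0]
        Syx, Syy, Syz = M[1]
        Szx, Szy, Szz = M[2]
        K = np.array([
            [Sxx + Syy + Szz, Szy - Syz, Sxz - Szx, Syx - Sxy],
            [Szy - Syz, Sxx - Syy - Szz, Sxy + Syx, Sxz + Szx],
            [Sxz - Szx, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Syx - Sxy, Sxz + Szx, Syz + Szy, -Sxx - Syy + Szz]])
        lam = np.linalg.eigvalsh(K)[-1]
        e0 = float(np.sum(ac ** 2) + np.sum(bc ** 2))
        oracle = math.sqrt(max(0.0, e0 - 2.0 * lam) / len(a))
        assert superpose_rmsd(conf(a), conf(b)) == pytest.approx(oracle, abs=1e-6)

    def test_mismatched_selection_rejected(self, helix):
        small = Conformer([helix.residues[0]])
        with pytest.raises(ValueError, match="mismatch"):
            superpose_rmsd(helix, small)

    def test_self_distance_zero(self):
        model = JunctionModel(seed=17)
        A = list(generate_library(model, 3))
        assert ensemble_distance(A, A) == pytest.approx(0.0, abs=1e-9)

    def test_singletons_reduce_to_pairwise_rmsd(self):
        a = generate_library(JunctionModel(seed=18), 1)[0]
        b = generate_library(JunctionModel(seed=19), 1)[0]
        assert ensemble_distance([a], [b]) == pytest.approx(
            superpose_rmsd(a, b), abs=1e-9)

    def test_matches_direct_definition_and_bounded_by_max(self):
        A = list(generate_library(JunctionModel(seed=20), 3))
        B = list(generate_library(JunctionModel(seed=22), 4))
        d = ensemble_distance(A, B)
        all_pairs = [superpose_rmsd(x, y) for x in A for y in B]

        def direct(X, Y):
            mins = [min(superpose_rmsd(x, y) for y in Y) for x in X]
            return math.sqrt(np.mean(np.square(mins)))

        oracle = min(direct(A, B), direct(B, A))
        assert d == pytest.approx(oracle, abs=1e-6)
        assert d <= max(all_pairs) + 1e-9
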