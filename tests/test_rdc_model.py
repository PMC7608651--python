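import numpy as np
import pytest

from rdcsas._geometry import rotation_y, rotation_z
from rdcsas.rdc_model import (AlignmentTensor, BondConstants, RDCDataset,
                              RDCRecord, ensemble_average, fit_scale_factors,
                              fit_svd_tensor, load_rdc_tsv, precompute_matrix,
                              predict_rdcs, rdc_rmsd, steric_tensor,
                              write_rdc_tsv)
from rdcsas.structures import Atom, Conformer, Residue


def _bond_conformer(vectors, pair=("C1'", "H1'"), bond=1.104):
    residues, records = [], []
    for i, v in enumerate(np.atleast_2d(vectors)):
        v = np.asarray(v, float)
        v = v / np.linalg.norm(v)
        residues.append(Residue(i + 1, "A", "A",
                                [Atom(pair[0], pair[0][0], (0.0, 0.0, 0.0)),
                                 Atom(pair[1], "H", bond * v)]))
        records.append(RDCRecord("x", i + 1, pair, 0.0))
    return Conformer(residues), RDCDataset(records)


def _random_tensor(rng, scale=5e-4):
    A = rng.normal(0, scale, (3, 3))
    S = 0.5 * (A + A.T)
    S -= np.eye(3) * np.trace(S) / 3.0
    return AlignmentTensor(S)


class TestAlignmentTensor:
    def test_symmetrized_and_traceless(self):
        t = AlignmentTensor(np.diag([1e-3, 1e-3, -2e-3]))
        assert abs(np.trace(t.saupe)) < 1e-12
        np.testing.assert_allclose(t.saupe, t.saupe.T)

    def test_asymmetric_input_rejected(self):
        M = np.zeros((3, 3))
        M[0, 1] = 1e-3
        with pytest.raises(ValueError):
            AlignmentTensor(M)

    def test_eigenvalue_ordering(self):
        t = AlignmentTensor(np.diag([2e-4, 1e-4, -3e-4]))
        w = t.eigenvalues
        assert abs(w[0]) >= abs(w[1]) >= abs(w[2])


class TestStericTensor:
    def _rod(self):
        residues = []
        k = 0
        for z in np.linspace(-40, 40, 41):
            for dx, dy in ((0, 0), (1.5, 0), (0, 1.5)):
                k += 1
                residues.append(Residue(k, "A", "A", [Atom("C1'", "C", (dx, dy, z))]))
        return Conformer(residues)

    def test_rod_is_axially_symmetric_along_rod(self):
        t = steric_tensor(self._rod(), orient_grid=10000)
        assert t.asymmetry < 0.05
        assert abs(t.principal_axes[:, 0][2]) > 0.999

    def test_grid_matches_dense_oracle_within_1pct(self):
        t = steric_tensor(self._rod(), orient_grid=10000)
        dense = steric_tensor(self._rod(), orient_grid=200000)
        rel = np.linalg.norm(t.saupe - dense.saupe) / np.linalg.norm(dense.saupe)
        assert rel < 0.01

    def test_rotation_equivariance(self):
        rod = self._rod()
        t = steric_tensor(rod, orient_grid=10000)
        R = rotation_z(25.0) @ rotation_y(70.0)
        t_rot = steric_tensor(rod.transformed(R, np.zeros(3)), orient_grid=10000)
        rel = (np.linalg.norm(t_rot.saupe - R @ t.saupe @ R.T)
               / np.linalg.norm(t.saupe))
        assert rel < 0.01

    def test_sphere_much_weaker_than_rod(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(600, 3))
        pts = 10 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        sphere = Conformer([Residue(i + 1, "A", "A", [Atom("C1'", "C", p)])
                            for i, p in enumerate(pts)])
        t_s = steric_tensor(sphere, orient_grid=10000)
        t_r = steric_tensor(self._rod(), orient_grid=10000)
        assert np.linalg.norm(t_s.saupe) < 1e-3 * np.linalg.norm(t_r.saupe)

    def test_collinear_coordinates_rejected(self):
        line = Conformer([Residue(i + 1, "A", "A",
                                  [Atom("C1'", "C", (0.0, 0.0, float(i)))])
                          for i in range(10)])
        with pytest.raises(ValueError, match="collinear"):
            steric_tensor(line)


class TestPredictRDCs:
    def test_bond_along_unique_axis_gives_dmax_szz(self):
        szz = 1e-3
        tensor = AlignmentTensor(np.diag([-szz / 2, -szz / 2, szz]))
        conf, ds = _bond_conformer([(0, 0, 1)])
        d = predict_rdcs(conf, tensor, ds)
        dmax = BondConstants().dmax("C1'", "H1'")
        np.testing.assert_allclose(d, [dmax * szz], rtol=1e-12)

    def test_magic_angle_gives_zero(self):
        szz = 1e-3
        tensor = AlignmentTensor(np.diag([-szz / 2, -szz / 2, szz]))
        cos_t = 1.0 / np.sqrt(3.0)
        u = (np.sqrt(1 - cos_t**2), 0.0, cos_t)
        conf, ds = _bond_conformer([u])
        d = predict_rdcs(conf, tensor, ds)
        dmax = BondConstants().dmax("C1'", "H1'")
        assert abs(d[0]) < 1e-9 * abs(dmax)

    def test_isotropic_average_vanishes(self):
        rng = np.random.default_rng(1)
        n = 40000
        tensor = _random_tensor(rng)
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        conf, ds = _bond_conformer(u)
        d = predict_rdcs(conf, tensor, ds)
        dmax = BondConstants().dmax("C1'", "H1'")
        scale = abs(dmax) * np.linalg.norm(tensor.saupe)
        assert abs(d.mean()) < 5.0 * scale / np.sqrt(n)

    def test_missing_atom_reported_with_location(self):
        conf, ds = _bond_conformer([(0, 0, 1)])
        bad = RDCDataset([RDCRecord("x", 99, ("C1'", "H1'"), 0.0)])
        with pytest.raises(KeyError, match="99"):
            predict_rdcs(conf, _random_tensor(np.random.default_rng(0)), bad)

    def test_unsupported_pair_type_rejected_by_name(self):
        ds = RDCDataset([RDCRecord("x", 1, ("P", "O5'"), 0.0)])
        conf, _ = _bond_conformer([(0, 0, 1)])
        with pytest.raises(ValueError, match="unsupported"):
            predict_rdcs(conf, _random_tensor(np.random.default_rng(0)), ds)

    def test_rotation_invariance_of_joint_rotation(self):
        rng = np.random.default_rng(3)
        tensor = _random_tensor(rng)
        u = rng.normal(size=(10, 3))
        conf, ds = _bond_conformer(u)
        R = rotation_z(33) @ rotation_y(41)
        d1 = predict_rdcs(conf, tensor, ds)
        d2 = predict_rdcs(conf.transformed(R, np.zeros(3)), tensor.rotated(R), ds)
        np.testing.assert_allclose(d1, d2, rtol=1e-10)


class TestEnsembleAverage:
    def test_single_two_and_mean(self, small_problem):
        m = small_problem["matrix"]
        np.testing.assert_array_equal(ensemble_average(m, [5]), m.values[5])
        np.testing.assert_array_equal(ensemble_average(m, [5, 5]), m.values[5])
        np.testing.assert_allclose(ensemble_average(m, [2, 9]),
                                   0.5 * (m.values[2] + m.values[9]))

    def test_permutation_invariance(self, small_problem):
        m = small_problem["matrix"]
        np.testing.assert_allclose(ensemble_average(m, [1, 7, 3]),
                                   ensemble_average(m, [3, 1, 7]))

    def test_empty_member_list_rejected(self, small_problem):
        with pytest.raises(ValueError):
            ensemble_average(small_problem["matrix"], [])


class TestScalesAndRmsd:
    def _dataset(self, values, construct="j1"):
        return RDCDataset([RDCRecord(construct, i + 1, ("C1'", "H1'"), float(v))
                           for i, v in enumerate(values)])

    def test_perfect_match_gives_unit_scale(self):
        ds = self._dataset([1.0, -2.0, 3.0])
        scales = fit_scale_factors(np.array([1.0, -2.0, 3.0]), ds)
        np.testing.assert_allclose(scales["j1"], 1.0)

    def test_doubled_data_gives_scale_two(self):
        ds = self._dataset([2.0, -4.0, 6.0])
        scales = fit_scale_factors(np.array([1.0, -2.0, 3.0]), ds)
        np.testing.assert_allclose(scales["j1"], 2.0)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(5)
        calc = rng.normal(size=30)
        exp = rng.normal(size=30)
        ds = self._dataset(exp)
        fitted = fit_scale_factors(calc, ds)["j1"]
        grid = np.linspace(fitted - 1.0, fitted + 1.0, 200001)
        costs = ((grid[:, None] * calc[None] - exp[None]) ** 2).sum(axis=1)
        assert abs(grid[np.argmin(costs)] - fitted) < 1e-4

    def test_all_zero_calc_degenerate(self):
        ds = self._dataset([1.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            fit_scale_factors(np.zeros(2), ds)

    def test_rmsd_zero_on_match_and_constant_residual(self):
        ds = self._dataset([1.0, -2.0, 3.0])
        assert rdc_rmsd(np.array([1.0, -2.0, 3.0]), ds, {"j1": 1.0}) == 0.0
        assert rdc_rmsd(np.array([3.0, 0.0, 5.0]), ds, {"j1": 1.0}) == pytest.approx(2.0)

    def test_rmsd_matches_direct_formula(self):
        rng = np.random.default_rng(6)
        calc = rng.normal(size=20)
        exp = rng.normal(size=20)
        ds = self._dataset(exp)
        L = 1.37
        ref = np.sqrt(np.mean((L * calc - exp) ** 2))
        assert rdc_rmsd(calc, ds, {"j1": L}) == pytest.approx(ref, abs=1e-12)

    def test_fitted_scale_never_beats_unit_scale(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            calc = rng.normal(size=15)
            exp = rng.normal(size=15)
            ds = self._dataset(exp)
            fitted = fit_scale_factors(calc, ds)
            assert rdc_rmsd(calc, ds, fitted) <= rdc_rmsd(calc, ds, None) + 1e-12

    def test_empty_subset_rejected(self):
        ds = self._dataset([1.0])
        with pytest.raises(ValueError):
            rdc_rmsd(np.array([1.0]), ds, None, subset=[])


class TestSVDFit:
    def test_noise_free_round_trip(self):
        rng = np.random.default_rng(2)
        truth = _random_tensor(rng)
        u = rng.normal(size=(20, 3))
        conf, probe = _bond_conformer(u)
        calc = predict_rdcs(conf, truth, probe)
        ds = RDCDataset([RDCRecord("x", i + 1, ("C1'", "H1'"), float(v))
                         for i, v in enumerate(calc)])
        fitted, rmsd, cond = fit_svd_tensor(ds, conf)
        rel = np.linalg.norm(fitted.saupe - truth.saupe) / np.linalg.norm(truth.saupe)
        assert rel < 1e-6
        assert rmsd < 1e-9
        assert cond >= 1.0

    def test_four_records_underdetermined(self):
        rng = np.random.default_rng(3)
        conf, _ = _bond_conformer(rng.normal(size=(4, 3)))
        ds = RDCDataset([RDCRecord("x", i + 1, ("C1'", "H1'"), 1.0)
                         for i in range(4)])
        with pytest.raises(ValueError):
            fit_svd_tensor(ds, conf)

    def test_degenerate_orientations_rejected(self):
        conf, _ = _bond_conformer([(0, 0, 1)] * 6)
        ds = RDCDataset([RDCRecord("x", i + 1, ("C1'", "H1'"), 1.0)
                         for i in range(6)])
        with pytest.raises(ValueError, match="underdetermined"):
            fit_svd_tensor(ds, conf)


class TestPrecomputeMatrix:
    def test_shape_and_consistency_with_standalone(self, small_problem):
        m = small_problem["matrix"]
        lib = small_problem["library"]
        ds = small_problem["dataset"]
        truth = small_problem["truth"]
        assert m.values.shape == (len(lib), len(ds))
        k = 4
        codes = ds.construct_codes()
        for j, cid in enumerate(ds.constructs):
            cols = np.flatnonzero(codes == j)
            direct = predict_rdcs(lib[k], truth.true_tensors[cid], ds.subset(cols))
            np.testing.assert_allclose(m.values[k, cols], direct, rtol=1e-12)

    def test_cache_round_trip_bit_identical(self, small_problem, tmp_path):
        lib = small_problem["library"]
        ds = small_problem["dataset"]
        truth = small_problem["truth"]
        m1 = precompute_matrix(lib, ds, mode="fixed-tensor",
                               tensors=truth.true_tensors, cache_dir=tmp_path)
        m2 = precompute_matrix(lib, ds, mode="fixed-tensor",
                               tensors=truth.true_tensors, cache_dir=tmp_path)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert len(list(tmp_path.glob("rdcmatrix_*.tsv"))) == 1

    def test_steric_mode_runs(self, small_problem):
        lib_small = small_problem["library"].conformers[:2]
        from rdcsas.structures import ConformerLibrary
        ds = small_problem["dataset"]
        m = precompute_matrix(ConformerLibrary(lib_small), ds, mode="steric",
                              orient_grid=500)
        assert np.all(np.isfinite(m.values))


class TestTabularIO:
    def test_tsv_round_trip(self, small_problem, tmp_path):
        ds = small_problem["dataset"]
        path = tmp_path / "rdc.tsv"
        write_rdc_tsv(ds, path)
        back = load_rdc_tsv(path)
        assert len(back) == len(ds)
        np.testing.assert_allclose(back.values(), ds.values())
        assert back.constructs == ds.constructs

    def test_duplicate_records_rejected(self):
        rec = RDCRecord("a", 1, ("C1'", "H1'"), 1.0)
        with pytest.raises(ValueError, match="duplicate"):
            RDCDataset([rec, rec])
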