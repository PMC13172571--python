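"""BAT transform and MIST configurational entropy."""
import numpy as np
import pytest

from densephase import entropy as E
from densephase.conformers import kabsch_rmsd
from densephase.errors import IncompatibleSystemsError, UndersamplingError


def _random_chain_frames(n_frames, n_atoms, seed=0, step=0.3):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, step, (n_frames, n_atoms, 3))
    return np.cumsum(steps, axis=1) + rng.normal(0, 2.0, (n_frames, 1, 3))


class TestBatTransform:
    def test_coordinate_counts_four_atom_chain(self):
        bat = E.bat_transform(_random_chain_frames(3, 4))
        assert bat.bonds.shape[1] == 3
        assert bat.angles.shape[1] == 2
        assert bat.torsions.shape[1] == 1
        assert bat.n_coordinates == 3 * 4 - 6

    def test_three_atom_molecule_has_no_torsions(self):
        bat = E.bat_transform(_random_chain_frames(2, 3))
        assert bat.torsions.shape[1] == 0

    def test_round_trip_to_machine_precision(self):
        coords = _random_chain_frames(10, 9, seed=3)
        rec = E.bat_reconstruct(E.bat_transform(coords))
        for f in range(10):
            assert kabsch_rmsd(rec[f], coords[f]) < 1e-9

    def test_cross_check_against_mdanalysis_bat(self):
        """Independent oracle: MDAnalysis' BAT analysis on the same chain."""
        import MDAnalysis as mda
        from MDAnalysis.analysis.bat import BAT as MdaBAT

        coords = _random_chain_frames(5, 6, seed=4)
        n = 6
        u = mda.Universe.empty(n, n_residues=1, atom_resindex=[0] * n,
                               trajectory=True)
        u.add_TopologyAttr("names", [f"C{i}" for i in range(n)])
        u.add_TopologyAttr("masses", [12.0] * n)
        u.add_TopologyAttr("bonds", [(i, i + 1) for i in range(n - 1)])
        u.load_new(coords * 10.0, format="memory")  # nm -> A
        mda_bat = MdaBAT(u.atoms).run()
        ours = E.bat_transform(coords)
        m = n - 3  # atoms beyond the root triplet
        for f in range(5):
            row = mda_bat.results.bat[f]
            # layout: 6 external | r01, r12, a012 | bonds | angles | torsions
            mda_bonds = np.concatenate([row[6:8], row[9:9 + m]]) / 10.0
            mda_angles = np.concatenate([row[8:9], row[9 + m:9 + 2 * m]])
            assert np.allclose(np.sort(ours.bonds[f]), np.sort(mda_bonds),
                               atol=1e-6)
            assert np.allclose(np.sort(ours.angles[f]), np.sort(mda_angles),
                               atol=1e-6)

    def test_rigid_body_invariance(self):
        from scipy.spatial.transform import Rotation

        coords = _random_chain_frames(4, 7, seed=5)
        rot = Rotation.random(random_state=np.random.default_rng(1)).as_matrix()
        moved = coords @ rot.T + np.array([3.0, -2.0, 1.0])
        a = E.bat_transform(coords)
        b = E.bat_transform(moved)
        assert np.allclose(a.bonds, b.bonds, atol=1e-12)
        assert np.allclose(a.angles, b.angles, atol=1e-12)
        assert np.allclose(np.abs(a.torsions), np.abs(b.torsions), atol=1e-9)


class TestMistEntropy:
    def test_independent_uniform_torsions(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(-np.pi, np.pi, size=(50_000, 4))
        res = E.mist_entropy(X, bins=30)
        # true marginal entropy ln(2 pi) each; MI ~ 0
        assert res.first_order == pytest.approx(4 * np.log(2 * np.pi), abs=0.02)
        assert res.S_mist == pytest.approx(res.first_order, abs=0.05)
        assert sum(w for _, _, w in res.tree_edges) < 0.02

    def test_duplicated_coordinate_absorbed_by_tree(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(-np.pi, np.pi, 20_000)
        y = rng.uniform(-np.pi, np.pi, 20_000)
        base = E.mist_entropy(np.stack([x, y], axis=1), bins=30)
        dup = E.mist_entropy(np.stack([x, y, x], axis=1), bins=30)
        # the tree uses the (0, 2) duplicate edge and its MI cancels the
        # copy's marginal up to the histogram discretization ln(width/bins)
        assert any({i, j} == {0, 2} for i, j, _ in dup.tree_edges)
        assert dup.S_mist == pytest.approx(
            base.S_mist + np.log(2 * np.pi / 30), abs=0.05)
        assert dup.S_mist <= dup.first_order

    def test_mist_never_exceeds_first_order(self, dense_result):
        coords = dense_result.unwrapped[:, :12, :]
        bat = E.bat_transform(coords)
        res = E.mist_entropy(bat, bins=12)
        assert res.S_mist <= res.first_order + 1e-12
        assert len(res.tree_edges) == res.marginals.size - 1

    def test_gaussian_pair_mutual_information(self):
        """MI of a rho=0.5 bivariate Gaussian is -ln(1-rho^2)/2 = 0.1438."""
        rng = np.random.default_rng(13)
        xy = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]],
                                     size=100_000)
        mi = E.pairwise_mi(xy[:, 0], xy[:, 1], bins=50)
        true = -0.5 * np.log(1 - 0.25)
        assert mi == pytest.approx(true, rel=0.10)

    def test_undersampled_rejected(self):
        X = np.random.default_rng(0).uniform(-1, 1, (50, 3))
        with pytest.raises(UndersamplingError):
            E.mist_entropy(X, bins=20)
        with pytest.raises(UndersamplingError):
            E.mist_entropy(np.random.default_rng(0).uniform(-1, 1, (120, 3)),
                           bins=200)

    def test_entropy_invariant_under_rigid_motion(self):
        coords = _random_chain_frames(300, 5, seed=8)
        moved = coords + np.array([5.0, 5.0, 5.0])
        a = E.mist_entropy(E.bat_transform(coords), bins=15)
        b = E.mist_entropy(E.bat_transform(moved), bins=15)
        assert a.S_mist == pytest.approx(b.S_mist, abs=1e-9)


class TestDeltaEntropy:
    def _ensemble(self, width, rng):
        tors = rng.uniform(-width, width, size=(400, 4))
        bonds = rng.normal(0.38, 0.01, size=(400, 6))
        angles = rng.normal(1.9, 0.05, size=(400, 5))
        return E.mist_entropy(E.BatCoordinates(bonds, angles, tors), bins=15)

    def test_identical_distributions_near_zero(self):
        rng = np.random.default_rng(9)
        singles = [self._ensemble(np.pi, rng) for _ in range(2)]
        denses = [self._ensemble(np.pi, rng) for _ in range(3)]
        delta = E.delta_entropy(singles, denses)
        assert abs(delta.mean) < 0.2  # estimator noise only

    def test_combination_count(self):
        rng = np.random.default_rng(10)
        singles = [self._ensemble(np.pi, rng) for _ in range(3)]
        denses = [self._ensemble(np.pi, rng) for _ in range(24)]
        delta = E.delta_entropy(singles, denses)
        assert delta.values.size == 72

    def test_restrained_ensemble_loses_entropy(self):
        rng = np.random.default_rng(11)
        singles = [self._ensemble(np.pi, rng) for _ in range(2)]
        denses = [self._ensemble(0.5, rng) for _ in range(3)]
        delta = E.delta_entropy(singles, denses, T=310.0)
        assert np.all(delta.values < 0)
        # conversion: nats * R * T / 1000 kcal/mol
        assert delta.TdS_kcal == pytest.approx(
            delta.mean * 1.98720 * 310.0 / 1000.0)

    def test_mismatched_coordinates_rejected(self):
        rng = np.random.default_rng(12)
        a = self._ensemble(np.pi, rng)
        small = E.mist_entropy(
            E.BatCoordinates(rng.normal(0.38, 0.01, (400, 3)),
                             rng.normal(1.9, 0.05, (400, 2)),
                             rng.uniform(-np.pi, np.pi, (400, 1))), bins=15)
        with pytest.raises(IncompatibleSystemsError):
            E.delta_entropy([a], [small])
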