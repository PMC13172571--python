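"""Fragment ensembles, gromos clustering, RMSF, Rg and SASA."""
import numpy as np
import pytest

from densephase import conformers as CF
from densephase.core import AtomRecord, Frame, SystemTopology, Trajectory
from densephase.errors import TopologyError


def _backbone_chain_topology(n_res, n_chains=1, L=20.0):
    chains = []
    for c in range(n_chains):
        atoms = []
        for r in range(n_res):
            for name, mass in (("N", 14.0), ("CA", 12.0), ("C", 12.0)):
                atoms.append(AtomRecord(c, r + 1, "GLY", name, True, mass, 0.16))
        chains.append(atoms)
    return SystemTopology(chains, ["G" * n_res] * n_chains, L)


def _helixish_coords(n_res, rng=None, jitter=0.0, seed=0):
    rng = rng or np.random.default_rng(seed)
    t = np.arange(n_res * 3) * 0.13
    coords = np.stack([np.cos(t), np.sin(t), 0.08 * np.arange(n_res * 3)],
                      axis=1) + 5.0
    if jitter:
        coords = coords + rng.normal(0, jitter, coords.shape)
    return coords


def _traj(coords_list, top):
    frames = [Frame(float(i), np.mod(c, top.box_edge), top.box_edge)
              for i, c in enumerate(coords_list)]
    return Trajectory(top, frames)


class TestFragmentEnsembles:
    def test_position_count_73mer_decamers(self):
        top = _backbone_chain_topology(73)
        traj = _traj([_helixish_coords(73)], top)
        ens = CF.fragment_ensembles([traj], w=10)
        assert len(ens) == 64
        assert min(ens) == 1 and max(ens) == 64

    def test_member_bookkeeping(self):
        top = _backbone_chain_topology(12, n_chains=3)
        base = _helixish_coords(12)
        trajs = []
        for rep in range(2):
            coords = np.concatenate([base + 2 * c + rep for c in range(3)])
            trajs.append(_traj([coords] * 5, top))
        ens = CF.fragment_ensembles(trajs, w=5, stride=1)
        # 2 replicas x 3 chains x 5 frames
        assert all(e.coordinates.shape[0] == 30 for e in ens.values())
        # members equal direct slicing of the source frames
        e1 = ens[3]
        rep, chain, frame = e1.labels[7]
        sl = top.chain_atoms(chain)
        src = trajs[rep].frames[frame].coordinates[sl].reshape(12, 3, 3)
        assert np.allclose(e1.coordinates[7], src[2:7].reshape(-1, 3))

    def test_missing_backbone_rejected(self):
        from conftest import make_point_topology

        top = make_point_topology([10], 10.0)  # CA-only beads
        traj = _traj([np.random.default_rng(0).uniform(0, 10, (10, 3))], top)
        with pytest.raises(TopologyError):
            CF.fragment_ensembles([traj], w=5)  # wants N, CA, C


def brute_force_gromos(coords, cutoff):
    """Independent oracle using scipy's superposition, plain loops."""
    from scipy.spatial.transform import Rotation

    n = len(coords)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a = coords[i] - coords[i].mean(axis=0)
            b = coords[j] - coords[j].mean(axis=0)
            rot, rssd = Rotation.align_vectors(b, a)
            dist[i, j] = dist[j, i] = rssd / np.sqrt(len(a))
    alive = set(range(n))
    clusters = []
    while alive:
        best, best_members = None, None
        for i in sorted(alive):
            members = {j for j in alive if dist[i, j] <= cutoff} | {i}
            if best is None or len(members) > len(best_members):
                best, best_members = i, members
        clusters.append(sorted(best_members))
        alive -= best_members
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return clusters


class TestGromosClustering:
    def test_three_identical_one_different(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(5, 3))
        other = rng.normal(size=(5, 3)) * 3.0  # different shape, not shift
        res = CF.gromos_clustering(np.stack([base, base, base, other]), 0.2)
        assert [len(c) for c in res.clusters] == [3, 1]
        assert res.top_occupancy == 75.0
        assert res.n_clusters == 2

    def test_all_identical(self):
        base = np.random.default_rng(1).normal(size=(4, 3))
        res = CF.gromos_clustering(np.stack([base] * 6), 0.1)
        assert res.n_clusters == 1 and res.top_occupancy == 100.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_neighbor_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        centers = rng.normal(size=(3, 4, 3))
        coords = np.stack([centers[rng.integers(3)]
                           + rng.normal(0, 0.05, (4, 3)) for _ in range(n)])
        got = CF.gromos_clustering(coords, 0.15).clusters
        want = brute_force_gromos(coords, 0.15)
        assert got == want

    def test_partition_property(self, dense_result):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(20, 5, 3))
        res = CF.gromos_clustering(coords, 0.8)
        flat = sorted(i for c in res.clusters for i in c)
        assert flat == list(range(20))


class TestRmsf:
    def test_rigid_ensemble_zero(self):
        top = _backbone_chain_topology(10)
        coords = _helixish_coords(10)
        traj = _traj([coords] * 6, top)
        ens = CF.fragment_ensembles([traj], w=5)
        profile = CF.rmsf_profile(ens, 5, 10)
        assert profile.shape == (10,)
        assert np.allclose(profile, 0.0, atol=1e-9)

    def test_jittered_residue_peaks(self):
        rng = np.random.default_rng(3)
        top = _backbone_chain_topology(12)
        base = _helixish_coords(12)
        frames = []
        sigma = 0.2
        for _ in range(60):
            c = base.copy()
            c[6 * 3:7 * 3] += rng.normal(0, sigma, (3, 3))  # residue 7 wobbles
            frames.append(c)
        traj = _traj(frames, top)
        ens = CF.fragment_ensembles([traj], w=5)
        profile = CF.rmsf_profile(ens, 5, 12)
        assert int(np.argmax(profile)) + 1 == 7
        # isotropic jitter of sigma per axis gives RMSF ~ sqrt(3) sigma
        assert profile[6] == pytest.approx(np.sqrt(3) * sigma, rel=0.25)


class TestRgAndSasa:
    def test_two_point_rg(self):
        from conftest import make_point_topology

        top = make_point_topology([2], 10.0)
        traj = _traj([np.array([[4.0, 5, 5], [6.0, 5, 5]])], top)
        rg = CF.rg_series(traj)
        assert rg[0, 0] == pytest.approx(1.0)

    def test_rg_rigid_motion_invariant(self):
        from scipy.spatial.transform import Rotation
        from conftest import make_point_topology

        rng = np.random.default_rng(4)
        pts = rng.normal(0, 0.5, (8, 3)) + 10.0
        top = make_point_topology([8], 40.0)
        rot = Rotation.random(random_state=rng).as_matrix()
        moved = (pts - pts.mean(0)) @ rot.T + pts.mean(0) + 3.0
        rgs = CF.rg_series(_traj([pts, moved], top))
        assert rgs[0, 0] == pytest.approx(rgs[1, 0], rel=1e-9)

    def test_sphere_sasa_closed_form(self):
        area = CF._sasa_of_group(np.zeros((1, 3)), np.array([0.2]), 0.14,
                                 CF._sphere_points(960))
        assert area == pytest.approx(4 * np.pi * 0.34 ** 2, rel=0.005)

    def test_two_spheres_occlusion_monotone(self):
        pts = CF._sphere_points(960)
        radii = np.array([0.2, 0.2])

        def area(sep):
            coords = np.array([[0.0, 0, 0], [sep, 0, 0]])
            return CF._sasa_of_group(coords, radii, 0.14, pts)

        # beyond the sum of expanded radii (0.68) there is no occlusion
        full = 2 * 4 * np.pi * 0.34 ** 2
        assert area(1.2) == pytest.approx(full, rel=0.005)
        areas = [area(sep) for sep in (0.6, 0.5, 0.4, 0.3)]
        assert all(a > b for a, b in zip(areas, areas[1:]))
        assert all(a < full for a in areas)

    def test_all_copies_mode_reports_per_chain_average(self):
        from conftest import make_point_topology

        top = make_point_topology([1, 1], 10.0)
        # far apart: the joint SASA equals two isolated spheres
        traj = _traj([np.array([[2.0, 2, 2], [8.0, 8, 8]])], top)
        per_chain = CF.sasa_series(traj, mode="per_chain")
        joint = CF.sasa_series(traj, mode="all_copies")
        assert joint[0, 0] == pytest.approx(per_chain[0].mean(), rel=1e-9)
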