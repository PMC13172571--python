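"""Contact rule, valency, coverage, clusters, lifetimes, enrichment."""
import numpy as np
import pytest

from densephase import contacts as C
from densephase.core import Frame, SystemTopology, Trajectory
from densephase.errors import (AlphabetError, ArgumentError,
                               DegenerateSeriesError)
from conftest import make_point_topology


def brute_force_contacts(coords, topology, cutoff, intra_exclusion):
    """Independent oracle: explicit 27-image enumeration per atom pair."""
    heavy = np.nonzero(topology.heavy_mask)[0]
    L = topology.box_edge
    shifts = [L * np.array([i, j, k]) for i in (-1, 0, 1)
              for j in (-1, 0, 1) for k in (-1, 0, 1)]
    records = set()
    for ii in range(len(heavy)):
        for jj in range(ii + 1, len(heavy)):
            i, j = heavy[ii], heavy[jj]
            dmin = min(np.linalg.norm(coords[j] + s - coords[i]) for s in shifts)
            if dmin > cutoff:
                continue
            ca, ra = int(topology.atom_chain[i]), int(topology.atom_res[i])
            cb, rb = int(topology.atom_chain[j]), int(topology.atom_res[j])
            if ca == cb and abs(ra - rb) < intra_exclusion:
                continue
            if (ca, ra) > (cb, rb):
                ca, ra, cb, rb = cb, rb, ca, ra
            records.add((ca, ra, cb, rb))
    return records


class TestFrameContacts:
    def test_cutoff_bracket(self):
        top = make_point_topology([1, 1], 10.0)
        near = Frame(0.0, np.array([[1.0, 1, 1], [1.34, 1, 1]]), 10.0)
        far = Frame(0.0, np.array([[1.0, 1, 1], [1.36, 1, 1]]), 10.0)
        assert len(C.frame_contacts(near, top).records) == 1
        assert len(C.frame_contacts(far, top).records) == 0

    def test_contact_across_boundary(self):
        top = make_point_topology([1, 1], 10.0)
        frame = Frame(0.0, np.array([[0.1, 0, 0], [9.9, 0, 0]]), 10.0)
        assert (0, 1, 1, 1) in C.frame_contacts(frame, top).records

    def test_intra_exclusion_skips_sequence_neighbors(self):
        top = make_point_topology([3], 10.0)
        frame = Frame(0.0, np.array([[0, 0, 0], [0.2, 0, 0], [0.2, 0.2, 0.0]]),
                      10.0)
        recs = C.frame_contacts(frame, top).records
        assert recs == {(0, 1, 0, 3)}

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_chains = 4
        n_res = 12  # one heavy atom per residue, 48 atoms; plus a few H
        L = 3.0
        from densephase.core import AtomRecord

        chains, coords = [], []
        for c in range(n_chains):
            atoms = []
            for r in range(n_res):
                atoms.append(AtomRecord(c, r + 1, "GLY", "CA", True, 57.0, 0.17))
                coords.append(rng.uniform(0, L, 3))
                if r % 3 == 0:  # hydrogens must never produce contacts
                    atoms.append(AtomRecord(c, r + 1, "GLY", "HA", False, 1.0, 0.12))
                    coords.append(rng.uniform(0, L, 3))
            chains.append(atoms)
        top = SystemTopology(chains, ["G" * n_res] * n_chains, L)
        frame = Frame(0.0, np.array(coords), L)
        got = C.frame_contacts(frame, top, cutoff=0.35).records
        want = brute_force_contacts(frame.coordinates, top, 0.35, 2)
        assert got == want


class TestValency:
    def _sets(self, edge_lists):
        out = []
        for f, edges in enumerate(edge_lists):
            out.append(C.ContactFrameSet(f, {(a, 1, b, 1) for a, b in edges}))
        return out

    def test_single_pair(self):
        vals = C.valency_series(self._sets([[(0, 1)]]), 3)
        assert vals.tolist() == [[1, 1, 0]]

    def test_fully_connected(self):
        edges = [(a, b) for a in range(4) for b in range(a + 1, 4)]
        vals = C.valency_series(self._sets([edges]), 4)
        assert vals.tolist() == [[3, 3, 3, 3]]

    def test_valency_sum_counts_connected_pairs(self, dense_contacts,
                                                dense_result):
        vals = C.valency_series(dense_contacts, 12)
        for f, cs in enumerate(dense_contacts):
            pairs = {(r[0], r[2]) for r in cs.inter()}
            assert vals[f].sum() == 2 * len(pairs)

    def test_acf_alternating_anticorrelation(self):
        series = np.tile([1.0, 0.0], 50)[:, None]
        fit = C.valency_acf(series, dt=1.0)
        assert fit.acf[1] == pytest.approx(-1.0, abs=1e-9)

    def test_acf_recovers_ar1_timescale(self):
        rho, dt = 0.8, 4.0
        rng = np.random.default_rng(3)
        x = np.zeros((4000, 6))
        for c in range(6):
            for t in range(1, 4000):
                x[t, c] = rho * x[t - 1, c] + rng.normal()
        fit = C.valency_acf(x, dt)
        assert fit.tau == pytest.approx(-dt / np.log(rho), rel=0.10)

    def test_constant_series_degenerate(self):
        with pytest.raises(DegenerateSeriesError):
            C.valency_acf(np.ones((50, 3)), dt=1.0)


class TestPairCoverage:
    def test_denominator_24_chains(self):
        assert C.chain_pair_count(24) == 276

    def test_extremes(self):
        empty = [C.ContactFrameSet(f, set()) for f in range(5)]
        times = np.arange(5.0)
        assert C.pair_coverage(empty, times, 4)[-1] == 0.0
        full = [C.ContactFrameSet(0, {(a, 1, b, 1) for a in range(4)
                                      for b in range(a + 1, 4)})]
        assert C.pair_coverage(full, times[:1], 4)[-1] == 1.0

    def test_matches_set_union_oracle_and_monotone(self):
        rng = np.random.default_rng(7)
        n_chains, n_frames = 8, 40
        sets, seen, want = [], set(), []
        for f in range(n_frames):
            edges = set()
            for _ in range(rng.integers(0, 4)):
                a, b = sorted(rng.choice(n_chains, 2, replace=False))
                edges.add((int(a), 1, int(b), 1))
            sets.append(C.ContactFrameSet(f, edges))
            seen |= {(e[0], e[2]) for e in edges}
            want.append(len(seen) / C.chain_pair_count(n_chains))
        got = C.pair_coverage(sets, np.arange(n_frames, dtype=float), n_chains)
        assert np.allclose(got, want)
        assert np.all(np.diff(got) >= 0)


class TestClusters:
    def test_transitive_component(self):
        top = make_point_topology([1] * 4, 10.0)
        frame = Frame(0.0, np.zeros((4, 3)), 10.0)
        traj = Trajectory(top, [frame])
        cs = [C.ContactFrameSet(0, {(0, 1, 1, 1), (1, 1, 2, 1)})]
        series = C.cluster_series(cs, traj)
        assert series.largest[0] == 3
        assert sorted(map(len, series.components[0])) == [1, 3]

    def test_no_edges_all_singletons(self):
        top = make_point_topology([1] * 4, 10.0)
        traj = Trajectory(top, [Frame(0.0, np.zeros((4, 3)), 10.0)])
        series = C.cluster_series([C.ContactFrameSet(0, set())], traj)
        assert series.largest[0] == 1
        assert not series.percolating[0]

    def _ring_system(self, spanning: bool):
        L = 6.0
        top = make_point_topology([8] * 3, L)
        if spanning:
            coords = np.concatenate(
                [[[(2 * c + i * 0.3) % L, 1.0, 1.0] for i in range(8)]
                 for c in range(3)])
        else:
            # chains 0-1 and 1-2 touch but the wrap link 2-0 is broken:
            # chain 2 is compressed so it stops 0.6 nm short of chain 0
            coords = np.concatenate(
                [[[(0.5 + 2 * c + i * 0.3) % L, 1.0, 1.0] for i in range(8)]
                 for c in range(2)]
                + [[[(4.7 + i * 0.17), 1.0, 1.0] for i in range(8)]])
        frame = Frame(0.0, np.mod(coords, L), L)
        return top, frame

    def test_percolation_through_boundary(self):
        top, frame = self._ring_system(True)
        cs = [C.frame_contacts(frame, top)]
        series = C.cluster_series(cs, Trajectory(top, [frame]))
        assert series.largest[0] == 3
        assert series.percolating[0]

    def test_open_chain_does_not_percolate(self):
        top, frame = self._ring_system(False)
        cs = [C.frame_contacts(frame, top)]
        series = C.cluster_series(cs, Trajectory(top, [frame]))
        assert series.largest[0] == 3  # still one connected cluster
        assert not series.percolating[0]


class TestLifetimes:
    def test_run_length_oracle(self):
        top = make_point_topology([1, 1], 5.0)
        pattern = [1, 1, 1, 0, 1, 0]
        sets = [C.ContactFrameSet(f, {(0, 1, 1, 1)} if p else set())
                for f, p in enumerate(pattern)]
        stats = C.contact_lifetimes(sets, stride=4.0, topology=top)
        st = stats[("G", "G")]
        assert sorted(st.durations) == [4.0, 12.0]
        assert st.mean == 8.0

    def test_always_present(self):
        top = make_point_topology([1, 1], 5.0)
        sets = [C.ContactFrameSet(f, {(0, 1, 1, 1)}) for f in range(7)]
        stats = C.contact_lifetimes(sets, stride=4.0, topology=top)
        assert stats[("G", "G")].durations == [28.0]

    def test_durations_sum_to_presence(self, dense_contacts, dense_result):
        top = dense_result.trajectory.topology
        stats = C.contact_lifetimes(dense_contacts, stride=10.0, topology=top)
        total = sum(sum(s.durations) for s in stats.values())
        presence = sum(len(cs.inter()) for cs in dense_contacts)
        assert total == pytest.approx(presence * 10.0)

    def test_sticker_contacts_outlive_spacer_contacts(self, dense_contacts,
                                                      dense_result):
        """Planted sticker-sticker contacts persist longer than spacer-spacer."""
        part = C.RegionPartition([(8, 12), (23, 27), (38, 42)], 60)
        top = dense_result.trajectory.topology
        stats = C.contact_lifetimes(dense_contacts, stride=10.0, topology=top,
                                    partition=part)
        assert stats[("ss",)].mean > stats[("pp",)].mean


class TestEnrichment:
    def test_expected_frequency_small_example(self):
        exp = C.expected_pair_frequency("GGRY")
        assert exp[("G", "G")] == pytest.approx(0.25)
        assert exp[("G", "R")] == pytest.approx(0.25)
        assert exp[("G", "Y")] == pytest.approx(0.25)
        assert exp[("R", "Y")] == pytest.approx(0.125)

    def test_homopolymer(self):
        assert C.expected_pair_frequency("AAAA") == {("A", "A"): 1.0}

    @pytest.mark.parametrize("seed", range(5))
    def test_expected_fractions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"),
                                 size=rng.integers(2, 50)))
        assert sum(C.expected_pair_frequency(seq).values()) == pytest.approx(1.0)

    def test_unknown_letter_rejected(self):
        with pytest.raises(AlphabetError):
            C.expected_pair_frequency("GGXB")

    def test_ratio_arithmetic(self):
        enr = C.pair_enrichment({("G", "G"): 2, ("G", "R"): 2}, "GGRY")
        by_pair = {e.pair: e.ratio for e in enr}
        assert by_pair[("G", "G")] == pytest.approx(2.0)

    def test_expected_distribution_gives_unit_ratios(self):
        seq = "GGRY"
        exp = C.expected_pair_frequency(seq)
        counts = {p: int(round(f * 1600)) for p, f in exp.items()}
        enr = C.pair_enrichment(counts, seq)
        assert all(e.ratio == pytest.approx(1.0) for e in enr)

    def test_planted_tyr_attraction_enriches_tyr_pairs(self, tyr_result):
        traj = tyr_result.trajectory
        cs = C.trajectory_contacts(traj)
        counts = C.observed_pair_counts(cs, traj.topology)
        enr = C.pair_enrichment(counts, traj.topology.sequences[0])
        top3 = [e.pair for e in enr[:3]]
        assert ("Y", "Y") in top3


class TestRegionPartition:
    def test_default_sticker_intervals_cover_claimed_ranges(self):
        part = C.RegionPartition(C.DEFAULT_STICKER_INTERVALS, 73)
        assert part.category(8) and part.category(17)
        assert not part.category(7) and not part.category(18)
        spacers = part.spacer_intervals
        assert spacers[0] == (1, 7)
        assert spacers[-1] == (71, 73)

    def test_trivial_fractions(self):
        part = C.RegionPartition([(1, 5)], 10)
        sets = [C.ContactFrameSet(0, {(0, 1, 1, 2), (0, 3, 1, 8),
                                      (0, 7, 1, 9), (0, 8, 1, 10)})]
        f_ss, f_sp, f_pp = C.region_contact_fractions(sets, part)
        assert (f_ss, f_sp, f_pp) == (0.25, 0.25, 0.5)

    def test_fractions_sum_to_one_against_membership_oracle(self,
                                                            dense_contacts):
        part = C.RegionPartition([(8, 12), (23, 27), (38, 42)], 60)
        f_ss, f_sp, f_pp = C.region_contact_fractions(dense_contacts, part)
        assert f_ss + f_sp + f_pp == pytest.approx(1.0, abs=1e-12)
        sticker_set = set()
        for s, e in part.sticker_intervals:
            sticker_set |= set(range(s, e + 1))
        n = {"ss": 0, "sp": 0, "pp": 0}
        for cs in dense_contacts:
            for _, ra, _, rb in cs.inter():
                k = (ra in sticker_set) + (rb in sticker_set)
                n[["pp", "sp", "ss"][k]] += 1
        total = sum(n.values())
        assert f_ss == pytest.approx(n["ss"] / total)
        assert f_sp == pytest.approx(n["sp"] / total)
        assert f_pp == pytest.approx(n["pp"] / total)
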