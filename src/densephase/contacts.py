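"""Contact detection, valency, clusters, lifetimes and enrichment.

A residue–residue contact exists when any two non-hydrogen atoms of the
two residues are within the cutoff (default 0.35 nm, inclusive) under
the minimum-image convention.  Intramolecular pairs closer than
``intra_exclusion`` in sequence (default: self and nearest neighbors)
are excluded, since those are trivially always in contact.

Instantaneous valency of a chain is the number of distinct partner
chains it touches in a frame.  Per-frame chain graphs (edge = any
inter-chain residue contact) drive cluster statistics; a cluster
percolates when the contact network connects a chain to its own
periodic image, i.e. some cycle in the graph carries a nonzero net
image displacement.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import SystemTopology, Trajectory, minimum_image_displacement
from .errors import (AlphabetError, ArgumentError, DegenerateSeriesError,
                     InconsistentSequenceError, InsufficientFramesError)

__all__ = [
    "ContactFrameSet", "AcfFit", "LifetimeStats", "PairEnrichment",
    "RegionPartition", "ClusterSeries", "DEFAULT_STICKER_INTERVALS",
    "frame_contacts", "trajectory_contacts", "valency_series", "valency_acf",
    "pair_coverage", "chain_pair_count", "cluster_series", "contact_lifetimes",
    "expected_pair_frequency", "pair_enrichment", "observed_pair_counts",
    "region_contact_fractions",
]

# Sticker intervals of the 73-residue FUS RGG3 fragment (1-based, inclusive),
# the reference partition for sticker/spacer statistics.
DEFAULT_STICKER_INTERVALS = ((8, 17), (24, 33), (37, 43), (48, 54), (64, 70))

Record = tuple[int, int, int, int]  # (chain_a, res_a, chain_b, res_b), a < b


@dataclass
class ContactFrameSet:
    """All residue–residue contacts of one frame.

    ``records`` holds lexicographically ordered ``(chain_a, res_a,
    chain_b, res_b)`` tuples; a record with ``chain_a == chain_b`` is an
    intramolecular contact.
    """

    frame_index: int
    records: set[Record] = field(default_factory=set)

    def inter(self) -> set[Record]:
        return {r for r in self.records if r[0] != r[2]}

    def intra(self) -> set[Record]:
        return {r for r in self.records if r[0] == r[2]}


def frame_contacts(frame, topology: SystemTopology, cutoff: float = 0.35,
                   intra_exclusion: int = 2, frame_index: int = 0,
                   ) -> ContactFrameSet:
    """Detect residue contacts in one frame by the heavy-atom cutoff rule."""
    heavy = topology.heavy_mask
    coords = frame.coordinates[heavy]
    chain = topology.atom_chain[heavy]
    res = topology.atom_res[heavy]
    L = frame.box_edge
    n = coords.shape[0]
    records: set[Record] = set()
    if n < 2:
        return ContactFrameSet(frame_index, records)
    # O(N^2) with minimum image, chunked to bound memory.
    chunk = max(1, int(4e6 // max(n, 1)))
    cut2 = cutoff * cutoff
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        d = coords[s:e, None, :] - coords[None, :, :]
        d -= L * np.round(d / L)
        d2 = np.einsum("ijk,ijk->ij", d, d)
        ii, jj = np.nonzero(d2 <= cut2)
        ii += s
        keep = ii < jj  # each unordered atom pair once
        for i, j in zip(ii[keep], jj[keep]):
            ca, ra, cb, rb = int(chain[i]), int(res[i]), int(chain[j]), int(res[j])
            if ca == cb:
                if abs(ra - rb) < intra_exclusion:
                    continue
            if (ca, ra) > (cb, rb):
                ca, ra, cb, rb = cb, rb, ca, ra
            records.add((ca, ra, cb, rb))
    return ContactFrameSet(frame_index, records)


def trajectory_contacts(traj: Trajectory, cutoff: float = 0.35,
                        intra_exclusion: int = 2) -> list[ContactFrameSet]:
    """Per-frame contact sets for a whole trajectory."""
    return [frame_contacts(f, traj.topology, cutoff, intra_exclusion, i)
            for i, f in enumerate(traj.frames)]


# ---------------------------------------------------------------------------
# valency
# ---------------------------------------------------------------------------

def valency_series(contact_sets: Sequence[ContactFrameSet], n_chains: int,
                   ) -> np.ndarray:
    """Instantaneous valency per chain per frame, shape (n_frames, n_chains)."""
    if not contact_sets:
        raise InsufficientFramesError("no frames to compute valency from")
    out = np.zeros((len(contact_sets), n_chains), dtype=int)
    for f, cs in enumerate(contact_sets):
        partners: list[set[int]] = [set() for _ in range(n_chains)]
        for ca, _, cb, _ in cs.inter():
            partners[ca].add(cb)
            partners[cb].add(ca)
        out[f] = [len(p) for p in partners]
    return out


@dataclass
class AcfFit:
    """Autocorrelation of a valency series plus a single-exponential fit."""

    lags: np.ndarray       # ps
    acf: np.ndarray        # normalized; acf[0] == 1
    tau: float             # ps
    amplitude: float
    fit_range: tuple[float, float]


def valency_acf(series: np.ndarray, dt: float, max_lag: float | None = None,
                ) -> AcfFit:
    """Chain-averaged, mean-removed valency ACF with exponential fit.

    Autocovariances are averaged over chains then normalized at lag zero;
    a single exponential ``A exp(-t/tau)`` is fit by unweighted least
    squares on lags up to the first zero crossing (or ``max_lag``,
    whichever comes first).
    """
    from scipy.optimize import curve_fit

    series = np.asarray(series, dtype=float)
    n_frames, n_chains = series.shape
    if n_frames < 10:
        raise InsufficientFramesError("valency ACF needs >= 10 frames")
    centered = series - series.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0):
        raise DegenerateSeriesError("valency series is constant")
    n_lags = n_frames // 2
    counts = n_frames - np.arange(n_lags)  # unbiased origin normalization
    acov = np.zeros(n_lags)
    for c in range(n_chains):
        x = centered[:, c]
        full = np.correlate(x, x, mode="full")[n_frames - 1:]
        acov += full[:n_lags] / counts
    acov /= n_chains
    acf = acov / acov[0]
    lags = np.arange(n_lags) * dt

    limit = n_lags
    crossing = np.nonzero(acf <= 0.0)[0]
    if crossing.size:
        limit = min(limit, int(crossing[0]))
    if max_lag is not None:
        limit = min(limit, int(np.floor(max_lag / dt)) + 1)
    limit = max(limit, 3)
    t_fit, y_fit = lags[:limit], acf[:limit]

    def model(t, amp, tau):
        return amp * np.exp(-t / tau)

    tau0 = max(dt, float(np.trapezoid(y_fit, t_fit)))
    popt, _ = curve_fit(model, t_fit, y_fit, p0=[1.0, tau0],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=10000)
    return AcfFit(lags=lags, acf=acf, tau=float(popt[1]),
                  amplitude=float(popt[0]),
                  fit_range=(float(t_fit[0]), float(t_fit[-1])))


# ---------------------------------------------------------------------------
# pair coverage
# ---------------------------------------------------------------------------

def chain_pair_count(n_chains: int) -> int:
    """Number of unordered chain pairs, n(n-1)/2 (24 chains -> 276)."""
    return n_chains * (n_chains - 1) // 2


def pair_coverage(contact_sets: Sequence[ContactFrameSet], times: np.ndarray,
                  n_chains: int, t_start: float = 0.0) -> np.ndarray:
    """Cumulative fraction of chain pairs contacted at least once.

    Returns the running fraction per frame (for frames at or after
    ``t_start``); its last entry is the total coverage.  Non-decreasing
    by construction.
    """
    times = np.asarray(times, dtype=float)
    if t_start > times[-1]:
        raise ArgumentError("t_start beyond the trajectory")
    denom = chain_pair_count(n_chains)
    seen: set[tuple[int, int]] = set()
    out = []
    for cs, t in zip(contact_sets, times):
        if t < t_start:
            continue
        for ca, _, cb, _ in cs.inter():
            seen.add((ca, cb))
        out.append(len(seen) / denom)
    return np.array(out)


# ---------------------------------------------------------------------------
# clusters and percolation
# ---------------------------------------------------------------------------

@dataclass
class ClusterSeries:
    """Per-frame chain partitions with largest sizes and percolation flags."""

    components: list[list[list[int]]]
    largest: np.ndarray
    percolating: np.ndarray


def cluster_series(contact_sets: Sequence[ContactFrameSet], traj: Trajectory,
                   ) -> ClusterSeries:
    """Single-linkage chain clusters per frame (= connected components).

    Percolation is detected geometrically: a spanning tree of each
    component assigns every chain an unwrapped anchor position; any
    non-tree contact edge whose minimum-image displacement disagrees with
    the tree assignment closes a cycle with nonzero net image shift, i.e.
    the component winds around the periodic box.
    """
    import networkx as nx

    top = traj.topology
    n_chains = top.n_chains
    L = traj.box_edge
    comps_all, largest, perc = [], [], []
    for f, cs in enumerate(contact_sets):
        g = nx.Graph()
        g.add_nodes_from(range(n_chains))
        g.add_edges_from((ca, cb) for ca, _, cb, _ in cs.inter())
        comps = [sorted(c) for c in nx.connected_components(g)]
        comps.sort(key=lambda c: (-len(c), c[0]))
        comps_all.append(comps)
        largest.append(len(comps[0]))
        # anchor = first atom of each chain (a consistent per-chain reference)
        anchors = np.stack([traj.frames[f].coordinates[top.chain_atoms(c)][0]
                            for c in range(n_chains)])
        perc.append(_percolates(g, anchors, L))
    return ClusterSeries(components=comps_all,
                         largest=np.array(largest, dtype=int),
                         percolating=np.array(perc, dtype=bool))


def _percolates(g, anchors: np.ndarray, L: float) -> bool:
    import networkx as nx

    pos: dict[int, np.ndarray] = {}
    for comp in nx.connected_components(g):
        comp = list(comp)
        root = comp[0]
        pos[root] = anchors[root].copy()
        for u, v in nx.bfs_edges(g, root):
            d = minimum_image_displacement(anchors[u], anchors[v], L)
            pos[v] = pos[u] + d
        sub = g.subgraph(comp)
        for u, v in sub.edges():
            d = minimum_image_displacement(anchors[u], anchors[v], L)
            if not np.allclose(pos[u] + d, pos[v], atol=1e-6):
                return True
    return False


# ---------------------------------------------------------------------------
# lifetimes
# ---------------------------------------------------------------------------

@dataclass
class LifetimeStats:
    """Uninterrupted contact durations aggregated under one key."""

    key: tuple
    durations: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.durations)) if self.durations else 0.0


def contact_lifetimes(contact_sets: Sequence[ContactFrameSet], stride: float,
                      topology: SystemTopology,
                      partition: "RegionPartition | None" = None,
                      intermolecular_only: bool = True,
                      ) -> dict[tuple, LifetimeStats]:
    """Run-length lifetimes of specific contacts, grouped by key.

    A run is a maximal stretch of consecutive frames over which a given
    ``(chain, res)-(chain, res)`` contact is present; a single absent
    frame terminates it (no gap tolerance).  Durations are
    ``run_length * stride`` ps.  Keys are unordered residue-type pairs,
    or region categories ('ss', 'sp', 'pp') when ``partition`` is given.
    """
    n_frames = len(contact_sets)
    presence: dict[Record, list[int]] = {}
    for f, cs in enumerate(contact_sets):
        recs = cs.inter() if intermolecular_only else cs.records
        for rec in recs:
            presence.setdefault(rec, []).append(f)

    stats: dict[tuple, LifetimeStats] = {}
    for rec, frames in presence.items():
        key = _lifetime_key(rec, topology, partition)
        st = stats.setdefault(key, LifetimeStats(key=key, durations=[]))
        run = 1
        for prev, cur in zip(frames, frames[1:]):
            if cur == prev + 1:
                run += 1
            else:
                st.durations.append(run * stride)
                run = 1
        st.durations.append(run * stride)
    return stats


def _lifetime_key(rec: Record, topology: SystemTopology,
                  partition: "RegionPartition | None") -> tuple:
    ca, ra, cb, rb = rec
    if partition is not None:
        a = partition.category(ra)
        b = partition.category(rb)
        return (("s" if a else "p") + ("s" if b else "p") if a >= b
                else ("s" if b else "p") + ("s" if a else "p"),)
    seq_a = topology.sequences[ca]
    seq_b = topology.sequences[cb]
    pair = tuple(sorted((seq_a[ra - 1], seq_b[rb - 1])))
    return pair


# ---------------------------------------------------------------------------
# composition-expected frequencies and enrichment
# ---------------------------------------------------------------------------

_AA = set("ACDEFGHIKLMNPQRSTVWY")


def expected_pair_frequency(sequence: str) -> dict[tuple[str, str], float]:
    """Expected contact fractions per unordered residue-type pair.

    Under composition-only statistics the expected fraction is
    ``n_A n_B / N^2`` for like pairs and ``2 n_A n_B / N^2`` for unlike
    pairs; the fractions sum to one.
    """
    if not sequence:
        raise ArgumentError("sequence is empty")
    bad = set(sequence) - _AA
    if bad:
        raise AlphabetError(f"unknown residue letters: {sorted(bad)}")
    N = len(sequence)
    counts: dict[str, int] = {}
    for a in sequence:
        counts[a] = counts.get(a, 0) + 1
    types = sorted(counts)
    out: dict[tuple[str, str], float] = {}
    for i, a in enumerate(types):
        for b in types[i:]:
            if a == b:
                out[(a, b)] = counts[a] * counts[b] / N ** 2
            else:
                out[(a, b)] = 2.0 * counts[a] * counts[b] / N ** 2
    return out


@dataclass
class PairEnrichment:
    pair: tuple[str, str]
    observed: float
    expected: float

    @property
    def ratio(self) -> float:
        return self.observed / self.expected


def observed_pair_counts(contact_sets: Sequence[ContactFrameSet],
                         topology: SystemTopology,
                         valency_filter: int | None = None,
                         ) -> dict[tuple[str, str], int]:
    """Inter-chain contact counts by unordered residue-type pair.

    With ``valency_filter`` set, only contacts whose two chains *both*
    have that exact valency in the frame are counted.
    """
    vals = None
    if valency_filter is not None:
        vals = valency_series(contact_sets, topology.n_chains)
    counts: dict[tuple[str, str], int] = {}
    for f, cs in enumerate(contact_sets):
        for ca, ra, cb, rb in cs.inter():
            if vals is not None and not (vals[f, ca] == valency_filter
                                         and vals[f, cb] == valency_filter):
                continue
            pair = tuple(sorted((topology.sequences[ca][ra - 1],
                                 topology.sequences[cb][rb - 1])))
            counts[pair] = counts.get(pair, 0) + 1
    return counts


def pair_enrichment(observed_counts: Mapping[tuple[str, str], int],
                    sequence: str) -> list[PairEnrichment]:
    """Observed/expected contact-type ratios, ranked descending.

    Ties in the ratio are broken alphabetically by pair label.
    """
    total = sum(observed_counts.values())
    if total <= 0:
        raise ArgumentError("no observed contacts")
    expected = expected_pair_frequency(sequence)
    out = []
    for pair, count in observed_counts.items():
        pair = tuple(sorted(pair))
        if expected.get(pair, 0.0) == 0.0:
            raise InconsistentSequenceError(
                f"observed pair {pair} impossible for this sequence")
        out.append(PairEnrichment(pair=pair, observed=count / total,
                                  expected=expected[pair]))
    out.sort(key=lambda e: (-e.ratio, e.pair))
    return out


# ---------------------------------------------------------------------------
# sticker/spacer partition
# ---------------------------------------------------------------------------

class RegionPartition:
    """Sticker intervals (1-based, inclusive) and their spacer complement."""

    def __init__(self, sticker_intervals: Iterable[tuple[int, int]], n_res: int):
        ivals = sorted((int(s), int(e)) for s, e in sticker_intervals)
        for (s, e) in ivals:
            if not (1 <= s <= e <= n_res):
                raise ArgumentError(f"interval {(s, e)} outside [1, {n_res}]")
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise ArgumentError("sticker intervals overlap")
        self.sticker_intervals = tuple(ivals)
        self.n_res = n_res
        mask = np.zeros(n_res + 1, dtype=bool)
        for s, e in ivals:
            mask[s:e + 1] = True
        self._sticker_mask = mask

    @property
    def spacer_intervals(self) -> tuple[tuple[int, int], ...]:
        out, start = [], 1
        for s, e in self.sticker_intervals:
            if s > start:
                out.append((start, s - 1))
            start = e + 1
        if start <= self.n_res:
            out.append((start, self.n_res))
        return tuple(out)

    def category(self, res: int) -> bool:
        """True for sticker, False for spacer."""
        return bool(self._sticker_mask[res])


def region_contact_fractions(contact_sets: Sequence[ContactFrameSet],
                             partition: RegionPartition,
                             ) -> tuple[float, float, float]:
    """Fractions of inter-chain contacts that are ss / sp / pp."""
    n_ss = n_sp = n_pp = 0
    for cs in contact_sets:
        for _, ra, _, rb in cs.inter():
            a, b = partition.category(ra), partition.category(rb)
            if a and b:
                n_ss += 1
            elif a or b:
                n_sp += 1
            else:
                n_pp += 1
    total = n_ss + n_sp + n_pp
    if total == 0:
        raise ArgumentError("no inter-chain contacts to classify")
    return n_ss / total, n_sp / total, n_pp / total
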