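"""Conformational statistics: fragment ensembles, clustering, RMSF, Rg, SASA.

Local structure is assessed on overlapping sequence fragments (pentamers
and decamers, single-residue shifts): every (replica, chain, sampled
frame) combination contributes one backbone conformation per fragment
position, the resulting ensembles are clustered with the iterative
neighbor-count ("gromos") algorithm at a fixed RMSD cutoff, and
per-residue RMSF profiles are reconstructed from the fragments' middle
residues.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import SystemTopology, Trajectory, minimum_image_displacement
from .errors import ArgumentError, TopologyError

__all__ = [
    "FragmentEnsemble", "ClusteringResult", "fragment_ensembles",
    "gromos_clustering", "rmsf_profile", "rg_series", "sasa_series",
    "kabsch_rmsd", "superpose",
]

BACKBONE_ATOMS = ("N", "CA", "C")


# ---------------------------------------------------------------------------
# rigid-body superposition
# ---------------------------------------------------------------------------

def _kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation aligning centered P onto centered Q."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Least-squares superposition of ``mobile`` onto ``reference``."""
    mc = mobile - mobile.mean(axis=0)
    rc = reference - reference.mean(axis=0)
    R = _kabsch_rotation(mc, rc)
    return mc @ R.T + reference.mean(axis=0)


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum RMSD between two conformations after optimal superposition."""
    fitted = superpose(a, b)
    return float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))


# ---------------------------------------------------------------------------
# fragment ensembles
# ---------------------------------------------------------------------------

@dataclass
class FragmentEnsemble:
    """Stacked backbone conformations of one fragment position."""

    start: int                 # 1-based first residue of the fragment
    window: int
    coordinates: np.ndarray    # (n_members, window*len(backbone), 3)
    labels: list[tuple[int, int, int]]  # (replica, chain, frame)
    backbone: tuple[str, ...] = BACKBONE_ATOMS


def _backbone_indices(top: SystemTopology, chain: int,
                      backbone: Sequence[str]) -> np.ndarray:
    """Flat atom indices of backbone atoms, residue-major order."""
    sl = top.chain_atoms(chain)
    atoms = top.atoms[sl]
    base = sl.start
    n_res = top.n_residues(chain)
    idx = np.full((n_res, len(backbone)), -1, dtype=int)
    name_pos = {n: k for k, n in enumerate(backbone)}
    for a_local, a in enumerate(atoms):
        k = name_pos.get(a.atom_name)
        if k is not None:
            idx[a.residue_index - 1, k] = base + a_local
    if np.any(idx < 0):
        raise TopologyError(
            f"chain {chain} lacks backbone atoms {backbone} in some residues")
    return idx


def _make_whole(coords: np.ndarray, L: float) -> np.ndarray:
    """Remove periodic jumps along a chain by walking from the first atom."""
    out = coords.copy()
    for i in range(1, len(out)):
        d = minimum_image_displacement(out[i - 1], coords[i], L)
        out[i] = out[i - 1] + d
    return out


def fragment_ensembles(trajs: Sequence[Trajectory], w: int, stride: int = 1,
                       backbone: Sequence[str] = BACKBONE_ATOMS,
                       ) -> dict[int, FragmentEnsemble]:
    """Build per-position fragment ensembles from (possibly many) replicas.

    Every replica, chain and sampled frame contributes one conformation
    per start position s in [1, n_res - w + 1].  Chains are made whole
    across the periodic boundary before slicing.
    """
    if w < 2:
        raise ArgumentError("fragment window must be >= 2")
    n_res = trajs[0].topology.n_residues(0)
    for t in trajs:
        if t.topology.n_residues(0) != n_res:
            raise ArgumentError("all trajectories must share the sequence length")
    if w > n_res:
        raise ArgumentError("window exceeds sequence length")
    starts = range(1, n_res - w + 2)
    members: dict[int, list[np.ndarray]] = {s: [] for s in starts}
    labels: dict[int, list[tuple[int, int, int]]] = {s: [] for s in starts}
    nb = len(backbone)
    for rep, traj in enumerate(trajs):
        top = traj.topology
        L = traj.box_edge
        bb = [(_backbone_indices(top, c, backbone)) for c in range(top.n_chains)]
        for f in range(0, traj.n_frames, stride):
            coords = traj.frames[f].coordinates
            for c in range(top.n_chains):
                chain_bb = coords[bb[c].ravel()].reshape(n_res, nb, 3)
                whole = _make_whole(chain_bb.reshape(-1, 3), L).reshape(n_res, nb, 3)
                for s in starts:
                    members[s].append(whole[s - 1:s - 1 + w].reshape(-1, 3))
                    labels[s].append((rep, c, f))
    return {s: FragmentEnsemble(start=s, window=w,
                                coordinates=np.stack(members[s]),
                                labels=labels[s], backbone=tuple(backbone))
            for s in starts}


# ---------------------------------------------------------------------------
# gromos clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    clusters: list[list[int]]   # member indices, sorted by size (desc)
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def top_occupancy(self) -> float:
        total = sum(len(c) for c in self.clusters)
        return 100.0 * len(self.clusters[0]) / total


def pairwise_rmsd_matrix(coords: np.ndarray) -> np.ndarray:
    n = len(coords)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = kabsch_rmsd(coords[i], coords[j])
    return m


def gromos_clustering(ensemble: FragmentEnsemble | np.ndarray,
                      cutoff: float) -> ClusteringResult:
    """Iterative neighbor-count clustering at a fixed RMSD cutoff.

    All pairs are superposed; repeatedly, the member with the most
    neighbors within the cutoff (ties: lowest index) is extracted together
    with its neighbors as a cluster until no member remains.  The result
    is a partition of the ensemble.
    """
    coords = (ensemble.coordinates if isinstance(ensemble, FragmentEnsemble)
              else np.asarray(ensemble))
    if len(coords) < 1:
        raise ArgumentError("empty ensemble")
    dist = pairwise_rmsd_matrix(coords)
    adj = dist <= cutoff
    np.fill_diagonal(adj, True)
    alive = np.ones(len(coords), dtype=bool)
    clusters: list[list[int]] = []
    while alive.any():
        counts = (adj & alive[None, :]).sum(axis=1)
        counts[~alive] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(adj[center] & alive)[0]
        clusters.append(members.tolist())
        alive[members] = False
    clusters.sort(key=lambda c: (-len(c), c[0]))
    return ClusteringResult(clusters=clusters, cutoff=cutoff)


# ---------------------------------------------------------------------------
# RMSF reconstruction
# ---------------------------------------------------------------------------

def rmsf_profile(ensembles: dict[int, FragmentEnsemble], w: int,
                 n_res: int) -> np.ndarray:
    """Per-residue RMSF from the middle residues of fragment ensembles.

    Members of each ensemble are superposed onto their mean (two passes);
    the backbone-averaged RMSF of the middle residue (3rd of a pentamer,
    5th of a decamer) is assigned to that sequence position.  Termini
    positions with no middle-residue assignment take the nearest assigned
    value.
    """
    middle = 3 if w == 5 else 5 if w == 10 else (w + 1) // 2
    profile = np.full(n_res, np.nan)
    for s, ens in ensembles.items():
        coords = ens.coordinates
        ref = coords[0]
        fitted = np.stack([superpose(c, ref) for c in coords])
        mean = fitted.mean(axis=0)
        fitted = np.stack([superpose(c, mean) for c in fitted])
        mean = fitted.mean(axis=0)
        per_atom = np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))
        nb = len(ens.backbone)
        res_rmsf = per_atom.reshape(ens.window, nb).mean(axis=1)
        profile[s - 1 + middle - 1] = res_rmsf[middle - 1]
    assigned = np.nonzero(np.isfinite(profile))[0]
    if assigned.size == 0:
        raise ArgumentError("no fragment positions assigned")
    for i in range(n_res):
        if not np.isfinite(profile[i]):
            profile[i] = profile[assigned[np.argmin(np.abs(assigned - i))]]
    return profile


# ---------------------------------------------------------------------------
# radius of gyration and SASA
# ---------------------------------------------------------------------------

def rg_series(traj: Trajectory) -> np.ndarray:
    """Mass-weighted radius of gyration per chain per frame (nm)."""
    top = traj.topology
    out = np.zeros((traj.n_frames, top.n_chains))
    for f, frame in enumerate(traj.frames):
        for c in range(top.n_chains):
            sl = top.chain_atoms(c)
            coords = _make_whole(frame.coordinates[sl], frame.box_edge)
            m = top.masses[sl]
            com = np.average(coords, axis=0, weights=m)
            out[f, c] = np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1),
                                           weights=m))
    return out


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi), np.cos(phi)], axis=1)


def _sasa_of_group(coords: np.ndarray, radii: np.ndarray, probe: float,
                   points: np.ndarray, L: float | None = None) -> float:
    """Shrake–Rupley SASA of one atom group (nm^2).

    With ``L`` set, occlusion distances use the minimum image (dense
    phase with mutual occlusion across the boundary).
    """
    n = len(coords)
    expanded = radii + probe
    area = 0.0
    for i in range(n):
        d = coords - coords[i]
        if L is not None:
            d -= L * np.round(d / L)
        dist2 = np.sum(d * d, axis=1)
        cut = (expanded[i] + expanded) ** 2
        neigh = np.nonzero((dist2 <= cut) & (dist2 > 0))[0]
        sphere = points * expanded[i]
        accessible = np.ones(len(points), dtype=bool)
        for j in neigh:
            dj = sphere - d[j]
            accessible &= np.sum(dj * dj, axis=1) > expanded[j] ** 2
            if not accessible.any():
                break
        frac = accessible.mean()
        area += frac * 4.0 * np.pi * expanded[i] ** 2
    return area


def sasa_series(traj: Trajectory, probe: float = 0.14, n_points: int = 960,
                mode: str = "per_chain", heavy_only: bool = True,
                ) -> np.ndarray:
    """Solvent-accessible surface area (nm^2) via Shrake–Rupley.

    ``mode='per_chain'`` treats each chain in isolation (dilute-phase
    reference); ``mode='all_copies'`` computes the SASA of all chains as
    one body under the minimum image (mutual occlusion) and divides by the
    chain count, returning a single column.
    """
    if mode not in ("per_chain", "all_copies"):
        raise ArgumentError("mode must be 'per_chain' or 'all_copies'")
    top = traj.topology
    points = _sphere_points(n_points)
    if mode == "per_chain":
        out = np.zeros((traj.n_frames, top.n_chains))
        for f, frame in enumerate(traj.frames):
            for c in range(top.n_chains):
                sl = top.chain_atoms(c)
                mask = top.heavy_mask[sl] if heavy_only else np.ones(
                    sl.stop - sl.start, dtype=bool)
                coords = _make_whole(frame.coordinates[sl], frame.box_edge)[mask]
                radii = top.vdw_radii[sl][mask]
                out[f, c] = _sasa_of_group(coords, radii, probe, points)
        return out
    out = np.zeros((traj.n_frames, 1))
    mask = top.heavy_mask if heavy_only else np.ones(top.n_atoms, dtype=bool)
    for f, frame in enumerate(traj.frames):
        total = _sasa_of_group(frame.coordinates[mask], top.vdw_radii[mask],
                               probe, points, L=frame.box_edge)
        out[f, 0] = total / top.n_chains
    return out
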