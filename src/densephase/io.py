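"""Standard-format I/O: PDB/GRO structures, XTC/DCD trajectories, FASTA.

MDAnalysis does the heavy lifting for every on-disk format; this module
only translates between its universes (Å) and the in-memory nm-based
:class:`~densephase.core.Trajectory` model, splits atoms into chains and
flags hydrogens.
"""
from __future__ import annotations

import os
import warnings
from typing import Sequence

import numpy as np

from .core import (AtomRecord, BONDI_RADII_NM, Frame, SystemTopology,
                   THREE_TO_ONE, Trajectory, infer_element, wrap_coordinates)
from .errors import ArgumentError, FormatError, UnsupportedGeometryError

__all__ = ["load_trajectory", "write_trajectory", "read_fasta", "write_fasta"]

_A_PER_NM = 10.0

_DEFAULT_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
                   "S": 32.06, "P": 30.974}


def _check_cubic(dimensions, tol: float = 1e-3) -> float:
    if dimensions is None:
        raise UnsupportedGeometryError("input has no box information")
    lx, ly, lz, alpha, beta, gamma = [float(x) for x in dimensions]
    if not (abs(alpha - 90) < 1e-3 and abs(beta - 90) < 1e-3 and abs(gamma - 90) < 1e-3):
        raise UnsupportedGeometryError("triclinic boxes are not supported")
    mean = (lx + ly + lz) / 3.0
    if max(abs(lx - mean), abs(ly - mean), abs(lz - mean)) > tol * mean:
        raise UnsupportedGeometryError(
            f"box edges {lx, ly, lz} differ by more than {tol:.1%}")
    return mean / _A_PER_NM


def _split_chains(universe, chain_definition) -> list[list[int]]:
    """Residue-index lists per chain from a per-chain residue-count list."""
    n_res = len(universe.residues)
    if chain_definition is None:
        counts = [n_res]
    elif np.isscalar(chain_definition):
        n_chains = int(chain_definition)
        if n_res % n_chains:
            raise ArgumentError(
                f"{n_res} residues not divisible into {n_chains} equal chains")
        counts = [n_res // n_chains] * n_chains
    else:
        counts = [int(c) for c in chain_definition]
    if sum(counts) != n_res:
        raise ArgumentError(
            f"chain definition {counts} does not cover {n_res} residues")
    out, start = [], 0
    for c in counts:
        out.append(list(range(start, start + c)))
        start += c
    return out


def load_trajectory(structure_file: str | os.PathLike,
                    trajectory_file: str | os.PathLike | None = None,
                    chain_definition: Sequence[int] | int | None = None,
                    ) -> Trajectory:
    """Load a PDB/GRO structure plus optional XTC/DCD trajectory.

    ``chain_definition`` gives the number of residues per chain (a list),
    or a chain count for equal-length chains, or ``None`` for one chain.
    Coordinates are converted to nm and wrapped into the primary box;
    hydrogens are flagged ``is_heavy=False`` by element inference from
    atom names.
    """
    import MDAnalysis as mda

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if trajectory_file is None:
                u = mda.Universe(str(structure_file))
            else:
                u = mda.Universe(str(structure_file), str(trajectory_file))
    except (OSError, ValueError, IOError) as exc:
        raise FormatError(f"could not load input files: {exc}") from exc

    L = _check_cubic(u.trajectory.ts.dimensions)
    res_chains = _split_chains(u, chain_definition)

    # residue -> (chain, 1-based index within chain)
    res_to_chain = {}
    for ci, residues in enumerate(res_chains):
        for k, ri in enumerate(residues):
            res_to_chain[ri] = (ci, k + 1)

    chains: list[list[AtomRecord]] = [[] for _ in res_chains]
    order: list[list[int]] = [[] for _ in res_chains]  # flat atom ordering
    for atom in u.atoms:
        elem = infer_element(atom.name)
        ci, rloc = res_to_chain[atom.residue.ix]
        mass = float(atom.mass) if atom.mass > 0 else _DEFAULT_MASSES.get(elem, 12.011)
        chains[ci].append(AtomRecord(
            chain_id=ci,
            residue_index=rloc,
            residue_name=str(atom.resname)[:3].upper(),
            atom_name=str(atom.name),
            is_heavy=(elem != "H"),
            mass=mass,
            vdw_radius=BONDI_RADII_NM.get(elem, 0.17),
        ))
        order[ci].append(atom.ix)
    atom_order = np.array([ix for chain in order for ix in chain], dtype=int)

    sequences = []
    for residues in res_chains:
        seq = "".join(THREE_TO_ONE.get(str(u.residues[ri].resname)[:3].upper(), "X")
                      for ri in residues)
        sequences.append(seq)

    topology = SystemTopology(chains, sequences, L)

    frames = []
    for ts in u.trajectory:
        Lf = _check_cubic(ts.dimensions)
        coords = wrap_coordinates(ts.positions[atom_order] / _A_PER_NM, Lf)
        frames.append(Frame(time=float(ts.time), coordinates=coords, box_edge=Lf))
    return Trajectory(topology, frames)


def write_trajectory(traj: Trajectory, structure_file: str | os.PathLike,
                     trajectory_file: str | os.PathLike | None = None) -> None:
    """Write a Trajectory as GRO/PDB (first frame) plus optional XTC/DCD."""
    import MDAnalysis as mda

    top = traj.topology
    n_atoms = top.n_atoms
    u = mda.Universe.empty(n_atoms, n_residues=sum(len(s) for s in top.sequences),
                           atom_resindex=_flat_resindex(top),
                           residue_segindex=_flat_segindex(top),
                           n_segments=top.n_chains, trajectory=True)
    u.add_TopologyAttr("names", [a.atom_name for a in top.atoms])
    resnames = []
    for chain in top.chains:
        seen = {}
        for a in chain:
            seen.setdefault(a.residue_index, a.residue_name)
        resnames.extend(v for _, v in sorted(seen.items()))
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", _resids(top))
    u.add_TopologyAttr("masses", [a.mass for a in top.atoms])
    u.add_TopologyAttr("segids", [f"C{c}" for c in range(top.n_chains)])

    L = traj.box_edge * _A_PER_NM
    dims = np.array([L, L, L, 90.0, 90.0, 90.0], dtype=np.float32)

    u.atoms.positions = traj.frames[0].coordinates * _A_PER_NM
    u.dimensions = dims
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(structure_file))
        if trajectory_file is not None:
            with mda.Writer(str(trajectory_file), n_atoms=n_atoms) as w:
                for frame in traj.frames:
                    u.atoms.positions = frame.coordinates * _A_PER_NM
                    u.trajectory.ts.dimensions = dims
                    u.trajectory.ts.time = frame.time
                    u.trajectory.ts.dt = traj.dt if traj.n_frames > 1 else 1.0
                    w.write(u.atoms)


def _flat_resindex(top: SystemTopology) -> np.ndarray:
    idx, offset = [], 0
    for ci, chain in enumerate(top.chains):
        n_res = len(top.sequences[ci])
        for a in chain:
            idx.append(offset + a.residue_index - 1)
        offset += n_res
    return np.array(idx, dtype=int)


def _flat_segindex(top: SystemTopology) -> np.ndarray:
    seg = []
    for ci, seq in enumerate(top.sequences):
        seg.extend([ci] * len(seq))
    return np.array(seg, dtype=int)


def _resids(top: SystemTopology) -> list[int]:
    ids = []
    for seq in top.sequences:
        ids.extend(range(1, len(seq) + 1))
    return ids


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read sequences from a FASTA file, keyed by record id."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
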