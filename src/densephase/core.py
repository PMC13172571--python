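"""Shared data model: topologies, frames, trajectories, periodic geometry.

Coordinates are stored in nanometres, times in picoseconds, masses in
daltons.  Boxes are cubic and coordinates of stored frames are wrapped
into the primary cell ``[0, L)``.  Residue numbering is 1-based within
each chain everywhere in this package.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ArgumentError, SamplingTooCoarseError

__all__ = [
    "AtomRecord",
    "SystemTopology",
    "Frame",
    "Trajectory",
    "Uncertainty",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_coordinates",
    "unwrap_chain_path",
    "propagate_error",
    "infer_element",
    "BONDI_RADII_NM",
    "RESIDUE_MASSES",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "sequence_mass",
]

# Bondi van der Waals radii, nm.
BONDI_RADII_NM = {
    "H": 0.120,
    "C": 0.170,
    "N": 0.155,
    "O": 0.152,
    "S": 0.180,
    "P": 0.180,
}

# Average residue masses (Da) of amino-acid residues *in chain* (monomer
# minus water); used for sequence molecular weights.
RESIDUE_MASSES = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLU": "E", "GLN": "Q", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


def sequence_mass(sequence: str) -> float:
    """Molecular weight (Da) of a peptide from its one-letter sequence."""
    return sum(RESIDUE_MASSES[a] for a in sequence) + WATER_MASS


_ELEMENT_RE = re.compile(r"[A-Za-z]")


def infer_element(atom_name: str) -> str:
    """Infer the element from a PDB v3 style atom name.

    Digits and primes are stripped; names like ``1HG1`` or ``HD21`` are
    hydrogens, ``CA`` is a carbon (calcium does not occur in protein
    chains), ``OW`` is a water oxygen.
    """
    stripped = [c for c in atom_name if c.isalpha()]
    if not stripped:
        raise ArgumentError(f"cannot infer element from atom name {atom_name!r}")
    return stripped[0].upper()


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a chain; ``residue_index`` is 1-based within the chain."""

    chain_id: int
    residue_index: int
    residue_name: str
    atom_name: str
    is_heavy: bool
    mass: float
    vdw_radius: float

    def __post_init__(self):
        if self.mass <= 0:
            raise ArgumentError("atom mass must be positive")
        if self.vdw_radius <= 0:
            raise ArgumentError("vdw radius must be positive")


class SystemTopology:
    """Chains of atoms in a cubic box of edge ``box_edge`` (nm).

    Per-atom numpy views (chain id, residue index, heavy flag, mass) are
    computed once and cached; they are what the contact and rheology code
    actually consumes.
    """

    def __init__(self, chains: Sequence[Sequence[AtomRecord]],
                 sequences: Sequence[str], box_edge: float):
        if box_edge <= 0:
            raise ArgumentError("box edge must be positive")
        self.chains = [list(c) for c in chains]
        self.sequences = list(sequences)
        self.box_edge = float(box_edge)
        atoms = [a for chain in self.chains for a in chain]
        self._atoms = atoms
        self.n_atoms = len(atoms)
        self.n_chains = len(self.chains)
        self.atom_chain = np.array([a.chain_id for a in atoms], dtype=np.int64)
        self.atom_res = np.array([a.residue_index for a in atoms], dtype=np.int64)
        self.heavy_mask = np.array([a.is_heavy for a in atoms], dtype=bool)
        self.masses = np.array([a.mass for a in atoms], dtype=float)
        self.vdw_radii = np.array([a.vdw_radius for a in atoms], dtype=float)
        # index range of each chain in the flat atom array
        sizes = [len(c) for c in self.chains]
        ends = np.cumsum(sizes)
        self.chain_slices = [slice(int(e - s), int(e)) for s, e in zip(sizes, ends)]

    @property
    def atoms(self) -> list[AtomRecord]:
        return self._atoms

    def chain_atoms(self, chain: int) -> slice:
        return self.chain_slices[chain]

    def n_residues(self, chain: int = 0) -> int:
        return len(self.sequences[chain])


@dataclass
class Frame:
    """Coordinates (nm) of one time point, wrapped into the primary box."""

    time: float
    coordinates: np.ndarray  # (n_atoms, 3)
    box_edge: float

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if not np.all(np.isfinite(self.coordinates)):
            raise ArgumentError("frame coordinates must be finite")


class Trajectory:
    """Time-ordered frames over a fixed topology with constant spacing."""

    def __init__(self, topology: SystemTopology, frames: Sequence[Frame]):
        frames = list(frames)
        if not frames:
            raise ArgumentError("trajectory needs at least one frame")
        times = np.array([f.time for f in frames])
        if len(frames) > 1:
            steps = np.diff(times)
            if np.any(steps <= 0):
                raise ArgumentError("frame times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise ArgumentError("frame spacing must be constant")
        self.topology = topology
        self.frames = frames
        self.times = times

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise ArgumentError("dt undefined for a single-frame trajectory")
        return float(self.times[1] - self.times[0])

    @property
    def box_edge(self) -> float:
        return self.frames[0].box_edge

    def coordinates(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class Uncertainty:
    """A value with a (non-negative) one-sigma uncertainty."""

    value: float
    eps: float = 0.0

    def __post_init__(self):
        if self.eps < 0:
            raise ArgumentError("uncertainty eps must be >= 0")


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def wrap_coordinates(coords: np.ndarray, L: float) -> np.ndarray:
    """Wrap coordinates into the primary cubic cell [0, L)."""
    return np.mod(coords, L)


def minimum_image_displacement(a: np.ndarray, b: np.ndarray, L: float) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a in a cubic box of edge L."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return d - L * np.round(d / L)


def minimum_image_distance(a, b, L: float):
    """Euclidean distance under the minimum-image convention.

    Accepts single 3-vectors or broadcastable arrays of them; the result is
    bounded by ``L * sqrt(3) / 2``.
    """
    if L <= 0:
        raise ArgumentError("box edge must be positive")
    d = minimum_image_displacement(a, b, L)
    return np.sqrt(np.sum(d * d, axis=-1))


def unwrap_chain_path(traj: Trajectory, chain: int,
                      mass_weighted: bool = True) -> np.ndarray:
    """Continuous (unwrapped) center-of-mass path of one chain.

    Each atom is unwrapped by accumulating minimum-image displacements
    between consecutive frames; the mass-weighted mean then lies on a
    continuous path.  Raises :class:`SamplingTooCoarseError` if any atom
    moves by >= L/2 along a coordinate between frames, since the true
    displacement is then aliased.
    """
    L = traj.box_edge
    sl = traj.topology.chain_atoms(chain)
    coords = traj.coordinates()[:, sl, :]
    masses = traj.topology.masses[sl]
    if not mass_weighted:
        masses = np.ones_like(masses)
    steps = coords[1:] - coords[:-1]
    mic = steps - L * np.round(steps / L)
    # |mic| close to L/2 means the displacement is ambiguous
    if mic.size and np.max(np.abs(mic)) >= 0.5 * L * (1 - 1e-9):
        raise SamplingTooCoarseError(
            "per-frame atomic displacement >= L/2; cannot unwrap unambiguously")
    unwrapped = np.concatenate([coords[:1], coords[:1] + np.cumsum(mic, axis=0)])
    w = masses / masses.sum()
    return np.einsum("fan,a->fn", unwrapped, w)


# ---------------------------------------------------------------------------
# error propagation
# ---------------------------------------------------------------------------

def propagate_error(partials: Iterable[float], eps: Iterable[float]) -> float:
    """First-order (Gaussian) error propagation.

    Returns ``sqrt(sum((df/dx_i * eps_i)**2))`` for independent inputs.
    """
    p = np.asarray(list(partials), dtype=float)
    e = np.asarray(list(eps), dtype=float)
    if p.shape != e.shape or p.ndim != 1 or p.size < 1:
        raise ArgumentError("partials and eps must be equal-length 1-D sequences")
    if np.any(e < 0):
        raise ArgumentError("eps values must be >= 0")
    return float(np.sqrt(np.sum((p * e) ** 2)))
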