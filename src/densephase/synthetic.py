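"""Synthetic inputs with known ground truth.

Three generators cover everything the analysis stages consume:

* ``generate_chain_trajectory`` — multi-chain bead-per-residue polymers
  evolved by Metropolis Monte Carlo with harmonic bonds, soft-core
  repulsion and a square-well attraction between designated "sticker"
  residues of *different* chains.  It emulates a dense phase of
  disordered chains with planted interaction motifs.
* ``generate_pressure_series`` — stationary Gaussian pressure-tensor
  series built from Ornstein–Uhlenbeck components, whose Green–Kubo
  viscosity is known in closed form.
* ``generate_brownian_tracks`` — free Brownian tracers with a known
  diffusion coefficient, for validating MSD estimators.

``build_multicopy_box`` reproduces the dense-phase construction
procedure: copies drawn from a monomer pool, randomly rotated, placed on
a regular grid without steric clashes.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import (AtomRecord, Frame, ONE_TO_THREE, RESIDUE_MASSES,
                   SystemTopology, Trajectory, minimum_image_distance,
                   sequence_mass, wrap_coordinates)
from .errors import (ArgumentError, InfeasibleSpecError, PlacementError,
                     ResolutionError)

__all__ = [
    "PolymerSpec", "OUSpec", "BrownianSpec",
    "SyntheticTrajectory", "generate_chain_trajectory",
    "build_multicopy_box", "generate_pressure_series",
    "generate_brownian_tracks", "KB_J_PER_K", "AVOGADRO",
]

KB_J_PER_K = 1.380649e-23
AVOGADRO = 6.02214076e23
CM2_PER_S_TO_NM2_PER_PS = 100.0  # 1 cm^2/s = 100 nm^2/ps

_DEFAULT_ALPHABET = "GRYD"  # Gly/Arg/Tyr/Asp cycle


@dataclass
class PolymerSpec:
    """Spec for the sticker-polymer Monte Carlo generator.

    ``mobility`` is the mean-squared proposal displacement per bead per
    sweep (nm^2); internally it maps to a uniform per-move half-width
    ``delta = sqrt(mobility)``.  ``sticker_strength`` is the square-well
    depth in kT acting between sticker beads of different chains, with
    well range ``1.5 x bead diameter``.
    """

    n_chains: int
    n_res: int
    box_edge: float
    bond_length: float = 0.38
    bead_radius: float = 0.26
    sticker_positions: frozenset = frozenset()
    sticker_strength: float = 0.0
    mobility: float = 0.01
    n_frames: int = 100
    frame_stride: int = 10
    seed: int = 0
    sequence: str | None = None
    bond_k: float = 200.0          # kT/nm^2
    repulsion_strength: float = 6.0  # kT at full overlap
    well_range_factor: float = 1.5   # in units of bead diameter
    n_equil_sweeps: int = 500
    ps_per_sweep: float = 1.0      # declared sweep -> time mapping

    def __post_init__(self):
        self.sticker_positions = frozenset(int(p) for p in self.sticker_positions)
        if self.sticker_positions and not (
                min(self.sticker_positions) >= 1
                and max(self.sticker_positions) <= self.n_res):
            raise ArgumentError("sticker positions must lie within [1, n_res]")
        if self.sticker_strength < 0:
            raise ArgumentError("sticker strength must be >= 0")
        if self.n_chains < 1 or self.n_res < 2:
            raise ArgumentError("need >= 1 chain of >= 2 residues")
        bead_vol = 4.0 / 3.0 * np.pi * self.bead_radius ** 3
        total = bead_vol * self.n_chains * self.n_res
        if total >= self.box_edge ** 3:
            raise InfeasibleSpecError("total bead volume exceeds box volume")
        if self.sequence is not None and len(self.sequence) != self.n_res:
            raise ArgumentError("sequence length must equal n_res")

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence
        return "".join(_DEFAULT_ALPHABET[i % len(_DEFAULT_ALPHABET)]
                       for i in range(self.n_res))

    @property
    def packing_fraction(self) -> float:
        bead_vol = 4.0 / 3.0 * np.pi * self.bead_radius ** 3
        return bead_vol * self.n_chains * self.n_res / self.box_edge ** 3


@dataclass
class OUSpec:
    """Ornstein–Uhlenbeck pressure-tensor spec with analytic viscosity.

    Each of the six tensor elements is an independent sum of OU
    components with autocovariance ``sum_k a_k exp(-t/tau_k)`` (a_k in
    bar^2, tau_k in ps), so the Green–Kubo integral is exactly
    ``sum_k a_k tau_k`` and eta_true follows in closed form.
    """

    components: Sequence[tuple[float, float]]
    dt: float
    n_steps: int
    V: float   # nm^3
    T: float = 310.0
    seed: int = 0

    def __post_init__(self):
        for a, tau in self.components:
            if a < 0 or tau <= 0:
                raise ArgumentError("OU amplitudes must be >= 0, timescales > 0")
        if self.dt <= 0 or self.n_steps < 2:
            raise ArgumentError("need positive dt and >= 2 steps")

    @property
    def eta_true(self) -> float:
        """Analytic Green–Kubo viscosity, mPa*s."""
        integral = sum(a * tau for a, tau in self.components)  # bar^2 ps
        return 1e-26 * self.V * integral / (KB_J_PER_K * self.T)


@dataclass
class BrownianSpec:
    """Free Brownian tracers with known diffusion coefficient (cm^2/s)."""

    D_true: float
    n_particles: int
    box_edge: float
    dt: float     # ps
    n_frames: int
    seed: int = 0

    def __post_init__(self):
        if self.D_true < 0:
            raise ArgumentError("D_true must be >= 0")
        if self.n_particles < 1 or self.n_frames < 2:
            raise ArgumentError("need >= 1 particle and >= 2 frames")


@dataclass
class SyntheticTrajectory:
    """A generated trajectory plus its unwrapped ground-truth paths."""

    trajectory: Trajectory
    unwrapped: np.ndarray  # (n_frames, n_atoms, 3), continuous coordinates
    ground_truth: dict = field(default_factory=dict)


def _bead_topology(spec: PolymerSpec) -> SystemTopology:
    seq = spec.resolved_sequence()
    chains = []
    for c in range(spec.n_chains):
        chain = [AtomRecord(chain_id=c, residue_index=i + 1,
                            residue_name=ONE_TO_THREE[seq[i]], atom_name="CA",
                            is_heavy=True,
                            mass=RESIDUE_MASSES[seq[i]],
                            vdw_radius=spec.bead_radius)
                 for i in range(spec.n_res)]
        chains.append(chain)
    return SystemTopology(chains, [seq] * spec.n_chains, spec.box_edge)


def _init_random_walks(spec: PolymerSpec, rng: np.random.Generator) -> np.ndarray:
    """Chains as fixed-bond random walks started on a regular grid."""
    m = int(np.ceil(spec.n_chains ** (1.0 / 3.0)))
    spacing = spec.box_edge / m
    sites = [(i, j, k) for i in range(m) for j in range(m) for k in range(m)]
    pos = np.empty((spec.n_chains * spec.n_res, 3))
    for c in range(spec.n_chains):
        i, j, k = sites[c]
        start = (np.array([i, j, k]) + 0.5) * spacing
        pos[c * spec.n_res] = start
        for r in range(1, spec.n_res):
            v = rng.normal(size=3)
            v *= spec.bond_length / np.linalg.norm(v)
            pos[c * spec.n_res + r] = pos[c * spec.n_res + r - 1] + v
    return pos


def generate_chain_trajectory(spec: PolymerSpec) -> SyntheticTrajectory:
    """Run the Metropolis MC polymer model and return the trajectory.

    Deterministic for a fixed ``spec.seed``.  The returned object carries
    both wrapped frames (as any file-based trajectory would) and the
    continuous ground-truth paths, so unwrapping code can be validated
    exactly.
    """
    from ._polymer_mc import run_polymer_mc

    if spec.packing_fraction > 0.4:
        raise InfeasibleSpecError(
            f"initial packing fraction {spec.packing_fraction:.2f} > 0.4")
    top = _bead_topology(spec)
    rng = np.random.default_rng(spec.seed)
    pos = _init_random_walks(spec, rng)
    is_sticker = np.zeros(top.n_atoms, dtype=np.bool_)
    for c in range(spec.n_chains):
        for p in spec.sticker_positions:
            is_sticker[c * spec.n_res + (p - 1)] = True
    delta = float(np.sqrt(spec.mobility))
    unwrapped = run_polymer_mc(
        pos, top.atom_chain, top.atom_res, is_sticker,
        spec.box_edge, spec.bond_length, spec.bond_k,
        2.0 * spec.bead_radius, spec.repulsion_strength,
        spec.well_range_factor * 2.0 * spec.bead_radius,
        spec.sticker_strength, delta, spec.n_equil_sweeps,
        spec.n_frames, spec.frame_stride, int(spec.seed) % (2 ** 31 - 1))
    frames = []
    dt = spec.frame_stride * spec.ps_per_sweep
    for f in range(spec.n_frames):
        frames.append(Frame(time=(f + 1) * dt,
                            coordinates=wrap_coordinates(unwrapped[f], spec.box_edge),
                            box_edge=spec.box_edge))
    traj = Trajectory(top, frames)
    return SyntheticTrajectory(traj, unwrapped,
                               ground_truth={"spec": spec,
                                             "sticker_positions": sorted(spec.sticker_positions)})


# ---------------------------------------------------------------------------
# multi-copy (dense-phase) box construction
# ---------------------------------------------------------------------------

def build_multicopy_box(monomer_pool: Sequence[tuple[Sequence[AtomRecord], np.ndarray]],
                        n_copies: int, box_edge: float, min_separation: float,
                        seed: int = 0, max_retries: int = 60,
                        ) -> tuple[SystemTopology, Frame, dict]:
    """Place randomly chosen, randomly oriented copies on a regular grid.

    ``monomer_pool`` holds candidate single-chain structures as
    ``(atom_records, coordinates_nm)`` tuples.  Copies are drawn with
    replacement, rotated by uniform random rotations and centered on the
    sites of a cubic grid; a placement is rejected (and re-rotated, up to
    ``max_retries`` times) if any heavy-atom pair of different copies
    comes within ``min_separation`` under the minimum image.

    Returns the combined topology, the assembled frame, and a report with
    the molar (mM) and mass (g/l) concentrations of the construction.
    """
    from scipy.spatial.transform import Rotation

    if not monomer_pool:
        raise ArgumentError("monomer pool is empty")
    rng = np.random.default_rng(seed)
    m = int(np.ceil(n_copies ** (1.0 / 3.0)))
    spacing = box_edge / m
    sites = np.array([(i, j, k) for i in range(m) for j in range(m)
                      for k in range(m)], dtype=float)
    sites = (sites + 0.5) * spacing
    order = rng.permutation(len(sites))[:n_copies]

    placed_heavy: list[np.ndarray] = []
    chains, sequences, frames_coords = [], [], []
    from .core import THREE_TO_ONE

    for copy_idx in range(n_copies):
        atoms, coords = monomer_pool[rng.integers(len(monomer_pool))]
        coords = np.asarray(coords, dtype=float)
        heavy = np.array([a.is_heavy for a in atoms], dtype=bool)
        centered = coords - coords.mean(axis=0)
        site = sites[order[copy_idx]]
        ok = False
        for _ in range(max_retries):
            rot = Rotation.random(random_state=rng).as_matrix()
            trial = centered @ rot.T + site
            if _clashes(trial[heavy], placed_heavy, box_edge, min_separation):
                continue
            ok = True
            break
        if not ok:
            raise PlacementError(
                f"copy {copy_idx}: no clash-free orientation in {max_retries} tries")
        placed_heavy.append(trial[heavy])
        chains.append([AtomRecord(chain_id=copy_idx, residue_index=a.residue_index,
                                  residue_name=a.residue_name, atom_name=a.atom_name,
                                  is_heavy=a.is_heavy, mass=a.mass,
                                  vdw_radius=a.vdw_radius) for a in atoms])
        seq = "".join(THREE_TO_ONE.get(a.residue_name, "X") for a in atoms
                      if a.atom_name in ("CA",)) or _seq_from_residues(atoms)
        sequences.append(seq)
        frames_coords.append(trial)

    top = SystemTopology(chains, sequences, box_edge)
    coords = wrap_coordinates(np.concatenate(frames_coords), box_edge)
    frame = Frame(time=0.0, coordinates=coords, box_edge=box_edge)

    chain_mass = float(sum(a.mass for a in chains[0]))
    v_liters = box_edge ** 3 * 1e-24
    molar = n_copies / (AVOGADRO * v_liters)
    info = {"molar_mM": molar * 1e3, "mass_g_per_l": molar * chain_mass,
            "chain_mass_Da": chain_mass, "grid": m, "spacing_nm": spacing}
    return top, frame, info


def _seq_from_residues(atoms) -> str:
    from .core import THREE_TO_ONE
    seen = {}
    for a in atoms:
        seen.setdefault(a.residue_index, a.residue_name)
    return "".join(THREE_TO_ONE.get(seen[k], "X") for k in sorted(seen))


def _clashes(new_heavy: np.ndarray, placed: list[np.ndarray], L: float,
             min_sep: float) -> bool:
    for other in placed:
        d = new_heavy[:, None, :] - other[None, :, :]
        d -= L * np.round(d / L)
        if np.min(np.sum(d * d, axis=-1)) < min_sep ** 2:
            return True
    return False


# ---------------------------------------------------------------------------
# pressure-tensor series (Ornstein–Uhlenbeck)
# ---------------------------------------------------------------------------

def generate_pressure_series(spec: OUSpec, strict: bool = False):
    """Six independent stationary OU sums emulating pressure fluctuations.

    Returns ``(PressureTensorSeries, eta_true)`` where eta_true is the
    closed-form Green–Kubo viscosity of the generating process (mPa*s).
    """
    import warnings

    from scipy.signal import lfilter

    from .rheology import PressureTensorSeries

    min_tau = min((tau for _, tau in spec.components), default=np.inf)
    if spec.dt >= min_tau / 5.0:
        msg = (f"dt={spec.dt} ps resolves the fastest component "
               f"(tau={min_tau} ps) with < 5 points per decay time")
        if strict:
            raise ResolutionError(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)

    rng = np.random.default_rng(spec.seed)
    series = np.zeros((spec.n_steps, 6))
    for elem in range(6):
        for a, tau in spec.components:
            if a == 0.0:
                continue
            phi = np.exp(-spec.dt / tau)
            innov_sd = np.sqrt(a * (1.0 - phi * phi))
            e = rng.normal(0.0, innov_sd, size=spec.n_steps)
            e[0] = rng.normal(0.0, np.sqrt(a))  # stationary start
            series[:, elem] += lfilter([1.0], [1.0, -phi], e)
    pts = PressureTensorSeries(dt=spec.dt, elements=series, V=spec.V, T=spec.T)
    return pts, spec.eta_true


# ---------------------------------------------------------------------------
# Brownian tracers
# ---------------------------------------------------------------------------

def generate_brownian_tracks(spec: BrownianSpec) -> SyntheticTrajectory:
    """Independent 3-D Brownian walkers, wrapped + unwrapped paths."""
    rng = np.random.default_rng(spec.seed)
    d_nm2_ps = spec.D_true * CM2_PER_S_TO_NM2_PER_PS
    sd = np.sqrt(2.0 * d_nm2_ps * spec.dt)
    start = rng.uniform(0.0, spec.box_edge, size=(1, spec.n_particles, 3))
    steps = rng.normal(0.0, sd, size=(spec.n_frames - 1, spec.n_particles, 3))
    unwrapped = np.concatenate([start, start + np.cumsum(steps, axis=0)])
    chains = [[AtomRecord(chain_id=p, residue_index=1, residue_name="GLY",
                          atom_name="CA", is_heavy=True, mass=1.0,
                          vdw_radius=0.17)] for p in range(spec.n_particles)]
    top = SystemTopology(chains, ["G"] * spec.n_particles, spec.box_edge)
    frames = [Frame(time=(f + 1) * spec.dt,
                    coordinates=wrap_coordinates(unwrapped[f], spec.box_edge),
                    box_edge=spec.box_edge)
              for f in range(spec.n_frames)]
    return SyntheticTrajectory(Trajectory(top, frames), unwrapped,
                               ground_truth={"D_true_cm2_s": spec.D_true})
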