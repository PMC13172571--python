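"""Fractal architecture of self-associated chain clusters.

Two chain-level observables — the mean interaction valency n and the
compactness (volume fraction) phi = V_mol / ((4/3) pi Rg^3) with
V_mol = kappa * M_w — determine the fractal dimension of the cluster
network:

    d_F = 3 / (1 - log(phi) / log(n + 1))

Iterating the aggregation (each generation multiplies the mass by n+1
and the radius by (n+1)^(1/d_F)) yields a power-law mass–size scaling
M ~ R^d_F valid at any cluster size.  A hierarchical cluster–cluster
aggregation generator produces explicit particle clusters obeying
N = k_f (Rg/a)^d_F for visualization and cross-checks.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, DomainError, GenerationError

__all__ = [
    "FractalState", "ScalingCurve", "FractalCluster", "KAPPA_A3_PER_DA",
    "volume_fraction", "fractal_dimension", "scaling_curve",
    "generate_fractal_cluster",
]

KAPPA_A3_PER_DA = 1.21  # van der Waals volume per unit mass, A^3/Da


def volume_fraction(M_w: float, R_g: float,
                    kappa: float = KAPPA_A3_PER_DA) -> float:
    """Compactness phi = kappa*M_w / ((4/3) pi Rg^3).

    kappa is in A^3/Da, so V_mol[nm^3] = kappa * M_w * 1e-3.  Values
    above 1 are physically possible for very compact conformers and are
    returned as-is (the fractal formula itself rejects them).
    """
    if M_w <= 0 or R_g <= 0:
        raise ArgumentError("M_w and R_g must be positive")
    v_mol = kappa * M_w * 1e-3  # nm^3
    return v_mol / (4.0 / 3.0 * np.pi * R_g ** 3)


def fractal_dimension(n: float, phi: float) -> float:
    """Fractal dimension from valency and volume fraction.

    ``d_F = 3 / (1 - log(phi)/log(n+1))``; the log base cancels.  Valid
    for n > 0 and 0 < phi < 1 (phi >= 1 breaks the premise that adding
    neighbors dilutes the cluster).
    """
    if n <= 0:
        raise DomainError("valency n must be positive")
    if not (0.0 < phi < 1.0):
        raise DomainError("volume fraction must lie in (0, 1) for this model")
    return 3.0 / (1.0 - np.log(phi) / np.log(n + 1.0))


@dataclass
class FractalState:
    """Chain-level observables tying a chain to its cluster topology."""

    n: float
    phi: float
    d_F: float
    R_g: float    # nm
    M_w: float    # Da
    kappa: float = KAPPA_A3_PER_DA

    @classmethod
    def from_observables(cls, n: float, R_g: float, M_w: float,
                         kappa: float = KAPPA_A3_PER_DA) -> "FractalState":
        phi = volume_fraction(M_w, R_g, kappa)
        return cls(n=n, phi=phi, d_F=fractal_dimension(n, phi), R_g=R_g,
                   M_w=M_w, kappa=kappa)


@dataclass
class ScalingCurve:
    masses: np.ndarray   # Da
    radii: np.ndarray    # nm
    slope: float         # d(log R)/d(log M) = 1/d_F
    intercept: float

    @property
    def d_F(self) -> float:
        return 1.0 / self.slope


def scaling_curve(state: FractalState, iterations: int) -> ScalingCurve:
    """Mass–size power law across aggregation generations.

    Generation k has mass ``(n+1)^k M_w`` and radius
    ``R_g ((n+1)^k)^(1/d_F)``; the log–log regression slope is 1/d_F by
    construction.
    """
    if iterations < 1:
        raise ArgumentError("need >= 1 iteration")
    k = np.arange(iterations + 1)
    growth = (state.n + 1.0) ** k
    masses = growth * state.M_w
    radii = state.R_g * growth ** (1.0 / state.d_F)
    slope, intercept = np.polyfit(np.log(masses), np.log(radii), 1)
    return ScalingCurve(masses=masses, radii=radii, slope=float(slope),
                        intercept=float(intercept))


# ---------------------------------------------------------------------------
# explicit cluster generator (hierarchical cluster–cluster aggregation)
# ---------------------------------------------------------------------------

@dataclass
class FractalCluster:
    coordinates: np.ndarray   # (n_particles, 3), monomer-radius units
    d_F_target: float
    k_f: float
    monomer_radius: float
    achieved_exponent: float
    hierarchy: list[tuple[int, float]]   # (N, Rg) at each merge level


def _rg_point(coords: np.ndarray) -> float:
    com = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - com) ** 2, axis=1))))


def generate_fractal_cluster(n_particles: int, d_F: float,
                             monomer_radius: float = 1.0, k_f: float = 1.0,
                             seed: int = 0, max_retries: int = 200,
                             ) -> FractalCluster:
    """Grow a particle cluster with a prescribed fractal dimension.

    Monomers are first paired at contact; cluster pairs are then merged
    hierarchically, each merge placing the partners at the center
    separation that makes the merged gyration radius satisfy
    ``N = k_f (Rg/a)^d_F``, subject to no two particles approaching
    closer than one monomer diameter (random orientations, bounded
    retries).  Deterministic for a fixed seed.
    """
    if not (1.0 < d_F < 3.0):
        raise DomainError("target d_F must lie in the open interval (1, 3)")
    if n_particles < 2:
        raise ArgumentError("need >= 2 particles")
    a = monomer_radius
    rng = np.random.default_rng(seed)
    clusters: list[np.ndarray] = [np.zeros((1, 3)) for _ in range(n_particles)]
    hierarchy: list[tuple[int, float]] = []
    while len(clusters) > 1:
        rng.shuffle(clusters)
        merged: list[np.ndarray] = []
        if len(clusters) % 2 == 1:
            merged.append(clusters.pop())
        for i in range(0, len(clusters), 2):
            c1, c2 = clusters[i], clusters[i + 1]
            new = _merge_pair(c1, c2, d_F, a, k_f, rng, max_retries)
            merged.append(new)
            hierarchy.append((len(new), _rg_point(new)))
        clusters = merged
    coords = clusters[0]
    sizes = np.array([n for n, _ in hierarchy], dtype=float)
    rgs = np.array([r for _, r in hierarchy], dtype=float)
    ok = rgs > 0
    if ok.sum() >= 2:
        slope = float(np.polyfit(np.log(rgs[ok] / a), np.log(sizes[ok]), 1)[0])
    else:
        slope = float("nan")
    return FractalCluster(coordinates=coords, d_F_target=d_F, k_f=k_f,
                          monomer_radius=a, achieved_exponent=slope,
                          hierarchy=hierarchy)


def _merge_pair(c1: np.ndarray, c2: np.ndarray, d_F: float, a: float,
                k_f: float, rng: np.random.Generator,
                max_retries: int) -> np.ndarray:
    n1, n2 = len(c1), len(c2)
    n = n1 + n2
    rg1, rg2 = _rg_point(c1), _rg_point(c2)
    rg_target = a * (n / k_f) ** (1.0 / d_F)
    gamma2 = (n * n / (n1 * n2)) * (rg_target ** 2
                                    - (n1 * rg1 ** 2 + n2 * rg2 ** 2) / n)
    gamma = np.sqrt(max(gamma2, 0.0))
    gamma = max(gamma, 2.0 * a)  # partners can never overlap at the COM level
    com1 = c1.mean(axis=0)
    base1 = c1 - com1
    base2 = c2 - c2.mean(axis=0)
    min_d2 = (2.0 * a * (1.0 - 1e-9)) ** 2
    for _ in range(max_retries):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        rot = _random_rotation(rng)
        trial2 = base2 @ rot.T + com1 + gamma * u
        trial1 = base1 + com1
        d = trial1[:, None, :] - trial2[None, :, :]
        if np.min(np.einsum("ijk,ijk->ij", d, d)) >= min_d2:
            return np.concatenate([trial1, trial2])
    raise GenerationError(
        f"could not merge clusters of {n1}+{n2} particles without overlap; "
        "retry with a different seed")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=rng).as_matrix()
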