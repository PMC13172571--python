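"""Shared fixtures: synthetic systems reused across test modules.

The Monte Carlo polymer runs are the expensive part of the suite, so the
standard planted-sticker system (12 chains of 60 residues, stickers at
10/25/40, 4 kT wells) and its contact sets are generated once per
session.
"""
import numpy as np
import pytest

from densephase import contacts as C
from densephase import synthetic as S

STICKERS = (10, 25, 40)


def planted_spec(seed: int, strength: float = 4.0, sequence=None,
                 n_frames: int = 150) -> S.PolymerSpec:
    return S.PolymerSpec(n_chains=12, n_res=60, box_edge=8.0,
                         sticker_positions=set(STICKERS),
                         sticker_strength=strength, n_frames=n_frames,
                         frame_stride=10, seed=seed, sequence=sequence)


@pytest.fixture(scope="session")
def dense_result():
    """Planted-sticker dense system, seed 1, default settings."""
    return S.generate_chain_trajectory(planted_spec(1))


@pytest.fixture(scope="session")
def dense_contacts(dense_result):
    return C.trajectory_contacts(dense_result.trajectory)


@pytest.fixture(scope="session")
def tyr_result():
    """Planted system whose sequence carries Tyr exactly at the stickers."""
    seq = "".join("Y" if i + 1 in STICKERS else "GRD"[i % 3] for i in range(60))
    return S.generate_chain_trajectory(planted_spec(2, sequence=seq,
                                                    n_frames=120))


@pytest.fixture(scope="session")
def ideal_result():
    """Same polymer with the sticker wells switched off (ideal mixing)."""
    return S.generate_chain_trajectory(planted_spec(3, strength=0.0,
                                                    n_frames=120))


@pytest.fixture(scope="session")
def ou_series_single():
    """Single-component OU pressure series (a=100 bar^2, tau=1 ps), seed 7."""
    spec = S.OUSpec(components=[(100.0, 1.0)], dt=0.01, n_steps=1_000_000,
                    V=27.0, T=310.0, seed=7)
    series, eta_true = S.generate_pressure_series(spec)
    return spec, series, eta_true


@pytest.fixture(scope="session")
def brownian_tracks():
    """64 Brownian tracers, D = 1e-6 cm^2/s, 5000 frames, seed 11."""
    spec = S.BrownianSpec(D_true=1.0e-6, n_particles=64, box_edge=15.0,
                          dt=10.0, n_frames=5000, seed=11)
    return spec, S.generate_brownian_tracks(spec)


def make_point_topology(positions_per_chain, box_edge, residue_names=None):
    """Topology of single-atom residues laid out explicitly (test helper)."""
    from densephase.core import AtomRecord, SystemTopology

    chains = []
    seqs = []
    for c, n_res in enumerate(positions_per_chain):
        names = (residue_names or ["GLY"] * n_res)
        chains.append([AtomRecord(chain_id=c, residue_index=i + 1,
                                  residue_name=names[i], atom_name="CA",
                                  is_heavy=True, mass=57.0, vdw_radius=0.17)
                       for i in range(n_res)])
        seqs.append("".join({"GLY": "G", "TYR": "Y", "ARG": "R",
                             "ASP": "D"}.get(n, "G") for n in names))
    return SystemTopology(chains, seqs, box_edge)
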