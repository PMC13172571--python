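"""Numba kernel for the Metropolis Monte Carlo bead-polymer generator.

Energies are in units of kT.  Positions are continuous (never wrapped);
all non-bonded interactions use the minimum image in a cubic box of edge
``L``.  Bonds use the direct difference, which is safe because chain
connectivity keeps consecutive beads within a small fraction of L.
"""
import numpy as np
from numba import njit


@njit(cache=False)
def _pair_energy(d2, r, is_st_i, is_st_j, same_chain, rep2, rep_r, eps_rep,
                 well2, eps_s):
    e = 0.0
    if d2 < rep2:
        t = 1.0 - r / rep_r
        e += eps_rep * t * t
    if eps_s > 0.0 and (not same_chain) and is_st_i and is_st_j and d2 < well2:
        e -= eps_s
    return e


@njit(cache=False)
def _bead_energy(pos, k, pk, chain_id, res_id, is_sticker, L, rep_r, eps_rep,
                 well_r, eps_s):
    """Non-bonded energy of bead k located at pk against all other beads."""
    n = pos.shape[0]
    rep2 = rep_r * rep_r
    well2 = well_r * well_r
    e = 0.0
    ck = chain_id[k]
    rk = res_id[k]
    stk = is_sticker[k]
    for j in range(n):
        if j == k:
            continue
        same = chain_id[j] == ck
        if same and abs(res_id[j] - rk) <= 1:
            continue  # bonded neighbors handled by the bond term
        dx = pos[j, 0] - pk[0]
        dy = pos[j, 1] - pk[1]
        dz = pos[j, 2] - pk[2]
        dx -= L * np.round(dx / L)
        dy -= L * np.round(dy / L)
        dz -= L * np.round(dz / L)
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < well2 or d2 < rep2:
            r = np.sqrt(d2)
            e += _pair_energy(d2, r, stk, is_sticker[j], same, rep2, rep_r,
                              eps_rep, well2, eps_s)
    return e


@njit(cache=False)
def _bond_energy(pos, k, pk, chain_id, res_id, b0, kbond):
    n = pos.shape[0]
    e = 0.0
    for j in (k - 1, k + 1):
        if 0 <= j < n and chain_id[j] == chain_id[k] and abs(res_id[j] - res_id[k]) == 1:
            dx = pos[j, 0] - pk[0]
            dy = pos[j, 1] - pk[1]
            dz = pos[j, 2] - pk[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            e += 0.5 * kbond * (r - b0) * (r - b0)
    return e


@njit(cache=False)
def run_polymer_mc(pos, chain_id, res_id, is_sticker, L, b0, kbond, rep_r,
                   eps_rep, well_r, eps_s, delta, n_equil_sweeps, n_frames,
                   frame_stride, seed):
    """Evolve beads by single-bead Metropolis moves; record n_frames."""
    np.random.seed(seed)
    n = pos.shape[0]
    out = np.empty((n_frames, n, 3))
    total_sweeps = n_equil_sweeps + n_frames * frame_stride
    frame = 0
    for sweep in range(total_sweeps):
        for k in range(n):
            old = pos[k].copy()
            new = np.empty(3)
            for d in range(3):
                new[d] = old[d] + delta * (2.0 * np.random.random() - 1.0)
            e_old = (_bead_energy(pos, k, old, chain_id, res_id, is_sticker, L,
                                  rep_r, eps_rep, well_r, eps_s)
                     + _bond_energy(pos, k, old, chain_id, res_id, b0, kbond))
            e_new = (_bead_energy(pos, k, new, chain_id, res_id, is_sticker, L,
                                  rep_r, eps_rep, well_r, eps_s)
                     + _bond_energy(pos, k, new, chain_id, res_id, b0, kbond))
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de):
                pos[k, 0] = new[0]
                pos[k, 1] = new[1]
                pos[k, 2] = new[2]
        if sweep >= n_equil_sweeps and (sweep - n_equil_sweeps + 1) % frame_stride == 0:
            out[frame] = pos
            frame += 1
    return out
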