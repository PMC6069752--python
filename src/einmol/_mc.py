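"""Numba kernels for single-particle-move Metropolis sampling.

One generic kernel covers every toy system in the package: per-atom
harmonic site restraints, a global truncated Lennard-Jones between atoms
of different molecules, harmonic bonds, and an optional soft-core coupled
solute atom.  Coefficients (λ scalings) are folded into the arrays before
the kernel is called, so the kernel itself knows nothing about alchemy.

Displacement steps are auto-tuned toward 30–50 % acceptance during the
equilibration window only; tuning stops at production to preserve
detailed balance.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["metropolis_chain"]


@njit(cache=False)
def _particle_energy(
    i,
    coords,
    box,
    mol_id,
    restr_ref,
    restr_k,
    lj_eps,
    lj_sigma,
    lj_cut2,
    sc_idx,
    sc_lam,
    sc_alpha,
    sc_eps,
    sc_sigma,
    sc_cut2,
    bond_i,
    bond_j,
    bond_k,
    bond_r0,
):
    e = 0.0
    if restr_k[i] > 0.0:
        dx = coords[i, 0] - restr_ref[i, 0]
        dy = coords[i, 1] - restr_ref[i, 1]
        dz = coords[i, 2] - restr_ref[i, 2]
        e += 0.5 * restr_k[i] * (dx * dx + dy * dy + dz * dz)
    n = coords.shape[0]
    for j in range(n):
        if j == i or mol_id[j] == mol_id[i]:
            continue
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        dx -= box[0] * np.rint(dx / box[0])
        dy -= box[1] * np.rint(dy / box[1])
        dz -= box[2] * np.rint(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if (i == sc_idx or j == sc_idx) and sc_idx >= 0:
            if sc_eps != 0.0 and sc_lam > 0.0 and r2 < sc_cut2:
                s6 = (r2 / (sc_sigma * sc_sigma)) ** 3
                denom = sc_alpha * (1.0 - sc_lam) ** 2 + s6
                e += 4.0 * sc_eps * sc_lam * (1.0 / (denom * denom) - 1.0 / denom)
        else:
            if lj_eps != 0.0 and r2 < lj_cut2:
                sr6 = (lj_sigma * lj_sigma / r2) ** 3
                e += 4.0 * lj_eps * (sr6 * sr6 - sr6)
    for b in range(bond_i.shape[0]):
        if bond_i[b] == i or bond_j[b] == i:
            a = bond_i[b]
            c = bond_j[b]
            dx = coords[a, 0] - coords[c, 0]
            dy = coords[a, 1] - coords[c, 1]
            dz = coords[a, 2] - coords[c, 2]
            dx -= box[0] * np.rint(dx / box[0])
            dy -= box[1] * np.rint(dy / box[1])
            dz -= box[2] * np.rint(dz / box[2])
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            e += 0.5 * bond_k[b] * (r - bond_r0[b]) ** 2
    return e


@njit(cache=False)
def metropolis_chain(
    coords0,
    box,
    mol_id,
    movable,
    restr_ref,
    restr_k,
    lj_eps,
    lj_sigma,
    lj_cutoff,
    sc_idx,
    sc_lam,
    sc_alpha,
    sc_eps,
    sc_sigma,
    sc_cutoff,
    bond_i,
    bond_j,
    bond_k,
    bond_r0,
    n_sweeps,
    n_equil,
    sample_every,
    step_init,
    seed,
):
    """Run a Metropolis chain; returns (samples, acceptance_rate, final_step).

    One sweep attempts ``len(movable)`` single-particle moves on randomly
    chosen movable atoms.  Configurations are recorded every
    ``sample_every`` sweeps after ``n_equil`` equilibration sweeps.
    """
    np.random.seed(seed)
    coords = coords0.copy()
    step = step_init
    n_mov = movable.shape[0]
    lj_cut2 = lj_cutoff * lj_cutoff
    sc_cut2 = sc_cutoff * sc_cutoff
    n_samples = (n_sweeps - n_equil + sample_every - 1) // sample_every
    out = np.empty((n_samples, coords.shape[0], 3))
    acc_prod = 0
    att_prod = 0
    acc_win = 0
    att_win = 0
    s = 0
    max_step = 0.45 * min(box[0], min(box[1], box[2]))
    for sweep in range(n_sweeps):
        for _m in range(n_mov):
            i = movable[np.random.randint(n_mov)]
            e_old = _particle_energy(
                i, coords, box, mol_id, restr_ref, restr_k,
                lj_eps, lj_sigma, lj_cut2,
                sc_idx, sc_lam, sc_alpha, sc_eps, sc_sigma, sc_cut2,
                bond_i, bond_j, bond_k, bond_r0,
            )
            ox = coords[i, 0]
            oy = coords[i, 1]
            oz = coords[i, 2]
            coords[i, 0] = ox + step * (2.0 * np.random.random() - 1.0)
            coords[i, 1] = oy + step * (2.0 * np.random.random() - 1.0)
            coords[i, 2] = oz + step * (2.0 * np.random.random() - 1.0)
            e_new = _particle_energy(
                i, coords, box, mol_id, restr_ref, restr_k,
                lj_eps, lj_sigma, lj_cut2,
                sc_idx, sc_lam, sc_alpha, sc_eps, sc_sigma, sc_cut2,
                bond_i, bond_j, bond_k, bond_r0,
            )
            de = e_new - e_old
            accept = False
            if de <= 0.0:
                accept = True
            elif np.random.random() < np.exp(-de):
                accept = True
            if accept:
                if sweep < n_equil:
                    acc_win += 1
                else:
                    acc_prod += 1
            else:
                coords[i, 0] = ox
                coords[i, 1] = oy
                coords[i, 2] = oz
            if sweep < n_equil:
                att_win += 1
            else:
                att_prod += 1
        if sweep < n_equil:
            if att_win >= 50 * n_mov:
                rate = acc_win / att_win
                if rate > 0.5:
                    step = min(step * 1.2, max_step)
                elif rate < 0.3:
                    step = step * 0.8
                acc_win = 0
                att_win = 0
        else:
            k = sweep - n_equil
            if k % sample_every == 0 and s < n_samples:
                for a in range(coords.shape[0]):
                    out[s, a, 0] = coords[a, 0]
                    out[s, a, 1] = coords[a, 1]
                    out[s, a, 2] = coords[a, 2]
                s += 1
    acc_rate = acc_prod / att_prod if att_prod > 0 else 0.0
    return out[:s], acc_rate, step
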