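"""Single-bead Metropolis Monte Carlo (numba kernel) and its drivers.

One sweep attempts one Gaussian move per bead in index order. The greedy
mode (energy minimisation) accepts only strictly downhill moves; the
Metropolis mode accepts with probability min(1, exp(-dE/kT)). All
randomness is drawn from a ``numpy`` PCG64 generator seeded once per run,
so trajectories are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .cg import MCState
from .model import EnergyModel


def _neighbour_list(pos, ev_active, cutoff):
    """Per-bead excluded-volume candidates within ``cutoff`` (Verlet list).

    Rebuilt every 100 sweeps; the 6 Å skin comfortably covers the maximum
    random-walk drift between rebuilds.
    """
    from scipy.spatial import cKDTree

    n = len(pos)
    pairs = cKDTree(pos).query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        keep = ev_active[pairs[:, 0], pairs[:, 1]] != 0
        pairs = pairs[keep]
    src = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else \
        np.empty(0, dtype=np.int64)
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else \
        np.empty(0, dtype=np.int64)
    order = np.argsort(src, kind="stable")
    counts = np.bincount(src, minlength=n) if len(src) else np.zeros(n, dtype=np.int64)
    start = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=start[1:])
    return start, dst[order].astype(np.int64)


@njit(cache=True)
def _bead_energy(i, pos, adj_start, adj_partner, adj_r0, k_bond,
                 tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
                 st_start, st_site, st_kind, st_k, st_R, st_axis, st_R2, ramp):
    e = 0.0
    xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
    for a in range(adj_start[i], adj_start[i + 1]):
        j = adj_partner[a]
        dx = xi - pos[j, 0]
        dy = yi - pos[j, 1]
        dz = zi - pos[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - adj_r0[a]
        e += 0.5 * k_bond * dr * dr
    tk = tether_k[i]
    if tk > 0.0:
        dx = xi - tether_ref[i, 0]
        dy = yi - tether_ref[i, 1]
        dz = zi - tether_ref[i, 2]
        e += 0.5 * tk * (dx * dx + dy * dy + dz * dz)
    for a in range(nb_start[i], nb_start[i + 1]):
        j = nb_idx[a]
        dx = xi - pos[j, 0]
        dy = yi - pos[j, 1]
        dz = zi - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < sigma * sigma:
            r = np.sqrt(r2)
            e += 0.5 * k_ev * (sigma - r) * (sigma - r)
    for a in range(st_start[i], st_start[i + 1]):
        dx = xi - st_site[a, 0]
        dy = yi - st_site[a, 1]
        dz = zi - st_site[a, 2]
        if st_kind[a] == 2 or st_kind[a] == 3:
            # repulsion from a finite disk (centre st_site, normal st_axis,
            # disk radius st_R2, shell thickness st_R). Kind 3 is
            # one-sided: only the -axis side and the wall itself are
            # penalised, with a lateral falloff beyond the rim so a chain
            # may detour around the ring edge.
            ax = (dx * st_axis[a, 0] + dy * st_axis[a, 1] + dz * st_axis[a, 2])
            px = dx - ax * st_axis[a, 0]
            py = dy - ax * st_axis[a, 1]
            pz = dz - ax * st_axis[a, 2]
            rad = np.sqrt(px * px + py * py + pz * pz) - st_R2[a]
            if rad < 0.0:
                rad = 0.0
            if st_kind[a] == 2:
                dd = np.sqrt(ax * ax + rad * rad)
                if dd < st_R[a]:
                    e += 0.5 * ramp * st_k[a] * (st_R[a] - dd) * (st_R[a] - dd)
            else:
                fall = 1.0 - rad / 3.0
                if fall > 0.0:
                    pen = (st_R[a] - ax) * fall
                    if pen > 0.0:
                        e += 0.5 * ramp * st_k[a] * pen * pen
            continue
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if st_kind[a] == 0:
            if r < st_R[a]:
                e += 0.5 * ramp * st_k[a] * (st_R[a] - r) * (st_R[a] - r)
        else:
            e += 0.5 * ramp * st_k[a] * r * r
    return e


@njit(cache=True)
def _run_sweeps(pos, adj_start, adj_partner, adj_r0, k_bond,
                tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
                st_start, st_site, st_kind, st_k, st_R, st_axis, st_R2, ramp,
                normals, uniforms, move_sigma, beta, greedy):
    n = pos.shape[0]
    accepted = 0
    for sw in range(normals.shape[0]):
        accepted += _sweep(pos, adj_start, adj_partner, adj_r0, k_bond,
                           tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
                           st_start, st_site, st_kind, st_k, st_R, st_axis,
                           st_R2, ramp, normals[sw], uniforms[sw], move_sigma,
                           beta, greedy)
    return accepted


@njit(cache=True)
def _sweep(pos, adj_start, adj_partner, adj_r0, k_bond,
           tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
           st_start, st_site, st_kind, st_k, st_R, st_axis, st_R2, ramp,
           normals, uniforms, move_sigma, beta, greedy):
    n = pos.shape[0]
    accepted = 0
    for i in range(n):
        e0 = _bead_energy(i, pos, adj_start, adj_partner, adj_r0, k_bond,
                          tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
                          st_start, st_site, st_kind, st_k, st_R, st_axis, st_R2, ramp)
        ox, oy, oz = pos[i, 0], pos[i, 1], pos[i, 2]
        pos[i, 0] = ox + move_sigma * normals[i, 0]
        pos[i, 1] = oy + move_sigma * normals[i, 1]
        pos[i, 2] = oz + move_sigma * normals[i, 2]
        e1 = _bead_energy(i, pos, adj_start, adj_partner, adj_r0, k_bond,
                          tether_k, tether_ref, nb_start, nb_idx, sigma, k_ev,
                          st_start, st_site, st_kind, st_k, st_R, st_axis, st_R2, ramp)
        de = e1 - e0
        if greedy:
            ok = de < 0.0
        else:
            ok = de <= 0.0 or uniforms[i] < np.exp(-beta * de)
        if ok:
            accepted += 1
        else:
            pos[i, 0] = ox
            pos[i, 1] = oy
            pos[i, 2] = oz
    return accepted


def run_mc(state: MCState, model: EnergyModel, sweeps: int,
           greedy: bool = False, ramp_from: float = 1.0, ramp_to: float = 1.0,
           rng: np.random.Generator = None, every: int = 0, callback=None,
           tether_ramp: tuple = None, stop_on_stall: bool = False,
           move_sigma: float = None) -> MCState:
    """Run ``sweeps`` Monte Carlo sweeps in place.

    ``ramp_from``/``ramp_to`` linearly scale the steering strengths over
    the run; ``tether_ramp=(mask, k0, k1)`` ramps the tether of the masked
    beads; ``callback(sweep)`` is invoked every ``every`` sweeps and may
    return True to terminate early.
    """
    s = model.settings
    if rng is None:
        rng = np.random.default_rng(state.seed)
    beta = 1.0 / s.kT
    if move_sigma is None:
        move_sigma = s.move_sigma
    n = state.n_beads
    chunk = 100
    done = 0
    while done < sweeps:
        m = min(chunk, sweeps - done)
        f = (done + 0.5 * m) / max(sweeps, 1)
        ramp = ramp_from + (ramp_to - ramp_from) * f
        if tether_ramp is not None:
            mask, k0, k1 = tether_ramp
            model.tether_k[mask] = k0 + (k1 - k0) * f
        nb_start, nb_idx = _neighbour_list(state.positions, model.ev_active,
                                           s.sigma_ev + 6.0)
        normals = rng.standard_normal((m, n, 3))
        uniforms = rng.random((m, n))
        acc = _run_sweeps(state.positions, model.adj_start, model.adj_partner,
                          model.adj_r0, s.k_bond, model.tether_k,
                          model.tether_ref, nb_start, nb_idx, s.sigma_ev,
                          s.k_ev, model.st_start, model.st_site, model.st_kind,
                          model.st_k, model.st_R, model.st_axis, model.st_R2,
                          ramp, normals, uniforms, move_sigma, beta, greedy)
        state.sweeps += m
        state.attempted += m * n
        state.accepted += int(acc)
        done += m
        if stop_on_stall and acc == 0:
            break
        if every and callback is not None and done % every < chunk:
            if callback(done):
                break
    return state


def minimize(state: MCState, model: EnergyModel, max_sweeps: int = None,
             rng: np.random.Generator = None, move_sigma: float = None) -> MCState:
    """Greedy downhill Monte Carlo: only energy-decreasing moves accepted."""
    if max_sweeps is None:
        max_sweeps = model.settings.sweeps_minimize
    return run_mc(state, model, max_sweeps, greedy=True, rng=rng,
                  stop_on_stall=True, move_sigma=move_sigma)
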