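"""Numba Metropolis Monte Carlo kernel for the coarse-grained model.

Single-site Gaussian displacement moves use O(n_sites) energy deltas with
incremental bookkeeping of the per-residue formed-contact weight (for the
Phi restraint); one rigid-body ligand move per sweep uses a full energy
recomputation.  The restraint acts on a *smooth* switching Phi_sim (a
sigmoid of the pair distance around the formed threshold) so that
fractional Phi targets are holdable; the discrete count used for reporting
is provided by :func:`contact_flags`.  All randomness comes from
``np.random`` seeded inside the kernel, so runs are bit-reproducible for a
given seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

KB = 1.98720425e-3  # kcal/mol/K
SWITCH_WIDTH = 0.015  # nm; sigmoid width of the smooth formed criterion


@njit(cache=True)
def _dist(x, i, j):
    dx = x[i, 0] - x[j, 0]
    dy = x[i, 1] - x[j, 1]
    dz = x[i, 2] - x[j, 2]
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _switch(r, cut):
    z = (r - cut) / SWITCH_WIDTH
    if z > 30.0:
        return 0.0
    if z < -30.0:
        return 1.0
    return 1.0 / (1.0 + np.exp(z))


@njit(cache=True)
def go_energy(x, bond_i, bond_j, bond_r0, bond_k,
              pair_i, pair_j, pair_r0, pair_eps,
              excl, sigma_rep, eps_rep, well_w):
    """Total Go energy: bonds + soft repulsion + native wells."""
    e = 0.0
    for b in range(len(bond_i)):
        d = _dist(x, bond_i[b], bond_j[b])
        dd = d - bond_r0[b]
        e += bond_k[b] * dd * dd
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            if excl[i, j]:
                continue
            d = _dist(x, i, j)
            if d < 1e-3:
                d = 1e-3
            if d < 2.5 * sigma_rep:
                q = sigma_rep / d
                q3 = q * q * q
                e += eps_rep * q3 * q3 * q3 * q3
    for p in range(len(pair_i)):
        d = _dist(x, pair_i[p], pair_j[p])
        dd = d - pair_r0[p]
        e -= pair_eps[p] * np.exp(-dd * dd / (2.0 * well_w * well_w))
    return e


@njit(cache=True)
def phi_state(x, pair_i, pair_j, pair_cut, pair_res_a, pair_res_b,
              pair_weight, n_res):
    """Smooth formed fraction per native pair and per-residue formed weight."""
    n_pairs = len(pair_i)
    fval = np.zeros(n_pairs)
    wform = np.zeros(n_res)
    for p in range(n_pairs):
        f = _switch(_dist(x, pair_i[p], pair_j[p]), pair_cut[p])
        fval[p] = f
        wform[pair_res_a[p]] += pair_weight[p] * f
        wform[pair_res_b[p]] += pair_weight[p] * f
    return fval, wform


@njit(cache=True)
def contact_flags(x, pair_i, pair_j, pair_cut):
    """Discrete formed flags per native pair (distance < threshold)."""
    n_pairs = len(pair_i)
    formed = np.zeros(n_pairs, dtype=np.bool_)
    for p in range(n_pairs):
        formed[p] = _dist(x, pair_i[p], pair_j[p]) < pair_cut[p]
    return formed


@njit(cache=True)
def phi_energy(wform, res_weight, phi_exp, k_phi):
    """k_phi * sum over restrained residues of (Phi_exp - Phi_sim)^2."""
    e = 0.0
    for r in range(len(phi_exp)):
        if not np.isnan(phi_exp[r]) and res_weight[r] > 0:
            d = phi_exp[r] - wform[r] / res_weight[r]
            e += d * d
    return k_phi * e


@njit(cache=True)
def _site_delta(x, xnew, s,
                sb_start, sb_bond, bond_i, bond_j, bond_r0, bond_k,
                sp_start, sp_pair, pair_i, pair_j, pair_r0, pair_eps,
                pair_cut, pair_res_a, pair_res_b, pair_weight,
                excl, sigma_rep, eps_rep, well_w,
                fval, wform, res_weight, phi_exp, k_phi,
                upd_pair, upd_f, aff_res, aff_dw):
    """Energy change for moving site s to xnew[s].

    Fills upd_pair/upd_f with the native pairs touching s and their new
    smooth formed fractions (returns their count) so an accepted move can
    update the bookkeeping incrementally.
    """
    de = 0.0
    for q in range(sb_start[s], sb_start[s + 1]):
        b = sb_bond[q]
        j = bond_j[b] if bond_i[b] == s else bond_i[b]
        dn = _dist(xnew, s, j)
        do = _dist(x, s, j)
        de += bond_k[b] * ((dn - bond_r0[b]) ** 2 - (do - bond_r0[b]) ** 2)
    n = len(x)
    for j in range(n):
        if excl[s, j]:
            continue
        do = _dist(x, s, j)
        dn = _dist(xnew, s, j)
        if do < 1e-3:
            do = 1e-3
        if dn < 1e-3:
            dn = 1e-3
        if do < 2.5 * sigma_rep:
            q = sigma_rep / do
            q3 = q * q * q
            de -= eps_rep * q3 * q3 * q3 * q3
        if dn < 2.5 * sigma_rep:
            q = sigma_rep / dn
            q3 = q * q * q
            de += eps_rep * q3 * q3 * q3 * q3
    # native wells + smooth contact bookkeeping
    n_upd = 0
    n_aff = 0
    for qq in range(sp_start[s], sp_start[s + 1]):
        p = sp_pair[qq]
        j = pair_j[p] if pair_i[p] == s else pair_i[p]
        do = _dist(x, s, j)
        dn = _dist(xnew, s, j)
        ddn = dn - pair_r0[p]
        ddo = do - pair_r0[p]
        de += pair_eps[p] * (
            np.exp(-ddo * ddo / (2.0 * well_w * well_w))
            - np.exp(-ddn * ddn / (2.0 * well_w * well_w))
        )
        fn = _switch(dn, pair_cut[p])
        df = fn - fval[p]
        upd_pair[n_upd] = p
        upd_f[n_upd] = fn
        n_upd += 1
        if k_phi > 0.0 and (df > 1e-12 or df < -1e-12):
            for rr in (pair_res_a[p], pair_res_b[p]):
                if np.isnan(phi_exp[rr]):
                    continue
                dwv = pair_weight[p] * df
                found = False
                for a in range(n_aff):
                    if aff_res[a] == rr:
                        aff_dw[a] += dwv
                        found = True
                        break
                if not found:
                    aff_res[n_aff] = rr
                    aff_dw[n_aff] = dwv
                    n_aff += 1
    for a in range(n_aff):
        rr = aff_res[a]
        w = res_weight[rr]
        d_old = phi_exp[rr] - wform[rr] / w
        d_new = phi_exp[rr] - (wform[rr] + aff_dw[a]) / w
        de += k_phi * (d_new * d_new - d_old * d_old)
    return de, n_upd


@njit(cache=True)
def run_sweeps(x, temps, seed,
               step_site, step_trans, step_rot,
               ligand_sites,
               sb_start, sb_bond, bond_i, bond_j, bond_r0, bond_k,
               sp_start, sp_pair, pair_i, pair_j, pair_r0, pair_eps,
               pair_cut, pair_res_a, pair_res_b, pair_weight,
               excl, sigma_rep, eps_rep, well_w,
               res_weight, phi_exp, k_phi,
               fval, wform):
    """Run len(temps) sweeps in place; returns acceptance counters
    (site_accepted, site_attempted, rigid_accepted, rigid_attempted)."""
    np.random.seed(seed)
    n = len(x)
    n_res = len(res_weight)
    xnew = x.copy()
    n_pairs = len(pair_i)
    upd_pair = np.empty(n_pairs, dtype=np.int64)
    upd_f = np.empty(n_pairs)
    aff_res = np.empty(2 * n_pairs + 1, dtype=np.int64)
    aff_dw = np.empty(2 * n_pairs + 1)
    acc_s = 0
    att_s = 0
    acc_r = 0
    att_r = 0
    n_lig = len(ligand_sites)
    for sweep in range(len(temps)):
        kt = KB * temps[sweep]
        for _ in range(n):
            s = np.random.randint(0, n)
            for d in range(3):
                xnew[s, d] = x[s, d] + step_site * np.random.standard_normal()
            de, n_upd = _site_delta(
                x, xnew, s,
                sb_start, sb_bond, bond_i, bond_j, bond_r0, bond_k,
                sp_start, sp_pair, pair_i, pair_j, pair_r0, pair_eps,
                pair_cut, pair_res_a, pair_res_b, pair_weight,
                excl, sigma_rep, eps_rep, well_w,
                fval, wform, res_weight, phi_exp, k_phi,
                upd_pair, upd_f, aff_res, aff_dw,
            )
            att_s += 1
            if de <= 0.0 or np.random.random() < np.exp(-de / kt):
                acc_s += 1
                for d in range(3):
                    x[s, d] = xnew[s, d]
                for u in range(n_upd):
                    p = upd_pair[u]
                    df = upd_f[u] - fval[p]
                    fval[p] = upd_f[u]
                    wform[pair_res_a[p]] += pair_weight[p] * df
                    wform[pair_res_b[p]] += pair_weight[p] * df
            else:
                for d in range(3):
                    xnew[s, d] = x[s, d]
        # one rigid-body ligand move per sweep
        if n_lig > 0:
            att_r += 1
            e_old = go_energy(x, bond_i, bond_j, bond_r0, bond_k,
                              pair_i, pair_j, pair_r0, pair_eps,
                              excl, sigma_rep, eps_rep, well_w)
            if k_phi > 0.0:
                e_old += phi_energy(wform, res_weight, phi_exp, k_phi)
            cx = 0.0
            cy = 0.0
            cz = 0.0
            for q in range(n_lig):
                s = ligand_sites[q]
                cx += x[s, 0]
                cy += x[s, 1]
                cz += x[s, 2]
            cx /= n_lig
            cy /= n_lig
            cz /= n_lig
            ax = np.random.standard_normal()
            ay = np.random.standard_normal()
            az = np.random.standard_normal()
            norm = np.sqrt(ax * ax + ay * ay + az * az)
            if norm < 1e-12:
                norm = 1.0
            ax /= norm
            ay /= norm
            az /= norm
            ang = step_rot * np.random.standard_normal()
            ca = np.cos(ang)
            sa = np.sin(ang)
            tx = step_trans * np.random.standard_normal()
            ty = step_trans * np.random.standard_normal()
            tz = step_trans * np.random.standard_normal()
            xtrial = x.copy()
            for q in range(n_lig):
                s = ligand_sites[q]
                px = x[s, 0] - cx
                py = x[s, 1] - cy
                pz = x[s, 2] - cz
                dot = ax * px + ay * py + az * pz
                rx = px * ca + (ay * pz - az * py) * sa + ax * dot * (1.0 - ca)
                ry = py * ca + (az * px - ax * pz) * sa + ay * dot * (1.0 - ca)
                rz = pz * ca + (ax * py - ay * px) * sa + az * dot * (1.0 - ca)
                xtrial[s, 0] = cx + rx + tx
                xtrial[s, 1] = cy + ry + ty
                xtrial[s, 2] = cz + rz + tz
            e_new = go_energy(xtrial, bond_i, bond_j, bond_r0, bond_k,
                              pair_i, pair_j, pair_r0, pair_eps,
                              excl, sigma_rep, eps_rep, well_w)
            fval_new, wform_new = phi_state(
                xtrial, pair_i, pair_j, pair_cut, pair_res_a, pair_res_b,
                pair_weight, n_res)
            if k_phi > 0.0:
                e_new += phi_energy(wform_new, res_weight, phi_exp, k_phi)
            de = e_new - e_old
            if de <= 0.0 or np.random.random() < np.exp(-de / kt):
                acc_r += 1
                for i in range(n):
                    for d in range(3):
                        x[i, d] = xtrial[i, d]
                        xnew[i, d] = xtrial[i, d]
                for p in range(n_pairs):
                    fval[p] = fval_new[p]
                for r in range(n_res):
                    wform[r] = wform_new[r]
    return acc_s, att_s, acc_r, att_r
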