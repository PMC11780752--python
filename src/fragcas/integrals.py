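"""McMurchie-Davidson evaluation of Gaussian one- and two-electron integrals.

Cartesian-Gaussian integrals over contracted shells via Hermite expansion
coefficients (E tables) and Boys-function R tensors, with numba-compiled
kernels at shell-pair / shell-quartet granularity.  Supports general angular
momentum in the recursions; the bundled basis sets use s and p shells.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import Shell, cartesian_components, component_factors, prim_norm

__all__ = ["overlap", "kinetic", "nuclear", "eri", "ao_integrals"]


@njit(cache=False)
def _boys(m_max, t, out):
    """Boys functions F_0..F_m_max(t) into ``out``."""
    if t < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2 * m + 1)
        return
    if t < 35.0:
        # series for the highest order, then downward recursion
        em = math.exp(-t)
        den = 2.0 * m_max + 1.0
        term = 1.0 / den
        ssum = term
        for _ in range(200):
            den += 2.0
            term *= 2.0 * t / den
            ssum += term
            if term < 1e-17 * ssum:
                break
        out[m_max] = em * ssum
        for m in range(m_max - 1, -1, -1):
            out[m] = (2 * t * out[m + 1] + em) / (2 * m + 1)
        return
    out[0] = 0.5 * math.sqrt(math.pi / t) * math.erf(math.sqrt(t))
    em = math.exp(-t)
    for m in range(m_max):
        out[m + 1] = ((2 * m + 1) * out[m] - em) / (2 * t)


@njit(cache=False)
def _e_table(imax, jmax, a, b, ab, out):
    """Hermite expansion coefficients E[i, j, t] for one dimension.

    ``ab = A - B``.  ``out`` must have shape (imax+1, jmax+1, imax+jmax+1).
    """
    p = a + b
    mu = a * b / p
    pa = -b * ab / p
    pb = a * ab / p
    out[:, :, :] = 0.0
    out[0, 0, 0] = math.exp(-mu * ab * ab)
    for i in range(imax + 1):
        for j in range(jmax + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                for t in range(i + j + 1):
                    v = pa * out[i - 1, 0, t]
                    if t > 0:
                        v += out[i - 1, 0, t - 1] / (2 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * out[i - 1, 0, t + 1]
                    out[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = pb * out[i, j - 1, t]
                    if t > 0:
                        v += out[i, j - 1, t - 1] / (2 * p)
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * out[i, j - 1, t + 1]
                    out[i, j, t] = v


@njit(cache=False)
def _r_table(lmax, p, x, y, z, out):
    """Hermite Coulomb integrals R_{t,u,v} (n=0) up to total order lmax."""
    t2 = p * (x * x + y * y + z * z)
    f = np.empty(lmax + 1)
    _boys(lmax, t2, f)
    prev = np.zeros((lmax + 1, lmax + 1, lmax + 1))
    cur = np.zeros((lmax + 1, lmax + 1, lmax + 1))
    for n in range(lmax, -1, -1):
        cur[:, :, :] = 0.0
        cur[0, 0, 0] = (-2.0 * p) ** n * f[n]
        rem = lmax - n
        for tt in range(rem + 1):
            for u in range(rem + 1 - tt):
                for v in range(rem + 1 - tt - u):
                    if tt == 0 and u == 0 and v == 0:
                        continue
                    if tt > 0:
                        val = x * prev[tt - 1, u, v]
                        if tt > 1:
                            val += (tt - 1) * prev[tt - 2, u, v]
                    elif u > 0:
                        val = y * prev[tt, u - 1, v]
                        if u > 1:
                            val += (u - 1) * prev[tt, u - 2, v]
                    else:
                        val = z * prev[tt, u, v - 1]
                        if v > 1:
                            val += (v - 1) * prev[tt, u, v - 2]
                    cur[tt, u, v] = val
        prev, cur = cur, prev
    out[:, :, :] = prev


@njit(cache=False)
def _pair_sk(la, lb, A, B, aexp, acoef, bexp, bcoef,
             ca_x, ca_y, ca_z, cb_x, cb_y, cb_z, fa, fb, s_out, t_out):
    """Overlap and kinetic blocks for one shell pair."""
    na, nb = len(ca_x), len(cb_x)
    s_out[:, :] = 0.0
    t_out[:, :] = 0.0
    emax = la + lb + 3
    ex = np.zeros((la + 1, lb + 3, emax + 1))
    ey = np.zeros((la + 1, lb + 3, emax + 1))
    ez = np.zeros((la + 1, lb + 3, emax + 1))
    for ip in range(len(aexp)):
        for jp in range(len(bexp)):
            a = aexp[ip]
            b = bexp[jp]
            p = a + b
            _e_table(la, lb + 2, a, b, A[0] - B[0], ex)
            _e_table(la, lb + 2, a, b, A[1] - B[1], ey)
            _e_table(la, lb + 2, a, b, A[2] - B[2], ez)
            pref = acoef[ip] * bcoef[jp] * (math.pi / p) ** 1.5
            for ia in range(na):
                for ib in range(nb):
                    i, k, m = ca_x[ia], ca_y[ia], ca_z[ia]
                    j, l_, n = cb_x[ib], cb_y[ib], cb_z[ib]
                    sx = ex[i, j, 0]
                    sy = ey[k, l_, 0]
                    sz = ez[m, n, 0]
                    tx = (-2.0 * b * b * ex[i, j + 2, 0]
                          + b * (2 * j + 1) * ex[i, j, 0])
                    if j >= 2:
                        tx -= 0.5 * j * (j - 1) * ex[i, j - 2, 0]
                    ty = (-2.0 * b * b * ey[k, l_ + 2, 0]
                          + b * (2 * l_ + 1) * ey[k, l_, 0])
                    if l_ >= 2:
                        ty -= 0.5 * l_ * (l_ - 1) * ey[k, l_ - 2, 0]
                    tz = (-2.0 * b * b * ez[m, n + 2, 0]
                          + b * (2 * n + 1) * ez[m, n, 0])
                    if n >= 2:
                        tz -= 0.5 * n * (n - 1) * ez[m, n - 2, 0]
                    fac = pref * fa[ia] * fb[ib]
                    s_out[ia, ib] += fac * sx * sy * sz
                    t_out[ia, ib] += fac * (tx * sy * sz + sx * ty * sz
                                            + sx * sy * tz)


@njit(cache=False)
def _pair_nuc(la, lb, A, B, aexp, acoef, bexp, bcoef,
              ca_x, ca_y, ca_z, cb_x, cb_y, cb_z, fa, fb,
              zs, coords, out):
    """Nuclear-attraction block for one shell pair (all nuclei)."""
    na, nb = len(ca_x), len(cb_x)
    out[:, :] = 0.0
    L = la + lb
    ex = np.zeros((la + 1, lb + 1, L + 1))
    ey = np.zeros((la + 1, lb + 1, L + 1))
    ez = np.zeros((la + 1, lb + 1, L + 1))
    r = np.zeros((L + 1, L + 1, L + 1))
    for ip in range(len(aexp)):
        for jp in range(len(bexp)):
            a = aexp[ip]
            b = bexp[jp]
            p = a + b
            px = (a * A[0] + b * B[0]) / p
            py = (a * A[1] + b * B[1]) / p
            pz = (a * A[2] + b * B[2]) / p
            _e_table(la, lb, a, b, A[0] - B[0], ex)
            _e_table(la, lb, a, b, A[1] - B[1], ey)
            _e_table(la, lb, a, b, A[2] - B[2], ez)
            cc = acoef[ip] * bcoef[jp] * 2.0 * math.pi / p
            for ic in range(len(zs)):
                _r_table(L, p, px - coords[ic, 0], py - coords[ic, 1],
                         pz - coords[ic, 2], r)
                for ia in range(na):
                    for ib in range(nb):
                        i, k, m = ca_x[ia], ca_y[ia], ca_z[ia]
                        j, l_, n = cb_x[ib], cb_y[ib], cb_z[ib]
                        v = 0.0
                        for t in range(i + j + 1):
                            for u in range(k + l_ + 1):
                                for w in range(m + n + 1):
                                    v += (ex[i, j, t] * ey[k, l_, u]
                                          * ez[m, n, w] * r[t, u, w])
                        out[ia, ib] -= zs[ic] * cc * v * fa[ia] * fb[ib]


@njit(cache=False)
def _quartet_eri(la, lb, lc, ld, A, B, C, D,
                 aexp, acoef, bexp, bcoef, cexp, ccoef, dexp, dcoef,
                 ca_x, ca_y, ca_z, cb_x, cb_y, cb_z,
                 cc_x, cc_y, cc_z, cd_x, cd_y, cd_z,
                 fa, fb, fc, fd, out):
    """(ab|cd) block for one shell quartet, chemists' notation."""
    na, nb = len(ca_x), len(cb_x)
    nc, nd = len(cc_x), len(cd_x)
    out[:, :, :, :] = 0.0
    lab = la + lb
    lcd = lc + ld
    L = lab + lcd
    e1x = np.zeros((la + 1, lb + 1, lab + 1))
    e1y = np.zeros((la + 1, lb + 1, lab + 1))
    e1z = np.zeros((la + 1, lb + 1, lab + 1))
    e2x = np.zeros((lc + 1, ld + 1, lcd + 1))
    e2y = np.zeros((lc + 1, ld + 1, lcd + 1))
    e2z = np.zeros((lc + 1, ld + 1, lcd + 1))
    r = np.zeros((L + 1, L + 1, L + 1))
    for ip in range(len(aexp)):
        for jp in range(len(bexp)):
            a = aexp[ip]
            b = bexp[jp]
            p = a + b
            px = (a * A[0] + b * B[0]) / p
            py = (a * A[1] + b * B[1]) / p
            pz = (a * A[2] + b * B[2]) / p
            _e_table(la, lb, a, b, A[0] - B[0], e1x)
            _e_table(la, lb, a, b, A[1] - B[1], e1y)
            _e_table(la, lb, a, b, A[2] - B[2], e1z)
            cab = acoef[ip] * bcoef[jp]
            for kp in range(len(cexp)):
                for lp in range(len(dexp)):
                    c = cexp[kp]
                    d = dexp[lp]
                    q = c + d
                    qx = (c * C[0] + d * D[0]) / q
                    qy = (c * C[1] + d * D[1]) / q
                    qz = (c * C[2] + d * D[2]) / q
                    _e_table(lc, ld, c, d, C[0] - D[0], e2x)
                    _e_table(lc, ld, c, d, C[1] - D[1], e2y)
                    _e_table(lc, ld, c, d, C[2] - D[2], e2z)
                    alpha = p * q / (p + q)
                    _r_table(L, alpha, px - qx, py - qy, pz - qz, r)
                    pref = (cab * ccoef[kp] * dcoef[lp]
                            * 2.0 * math.pi ** 2.5
                            / (p * q * math.sqrt(p + q)))
                    for ia in range(na):
                        i1, k1, m1 = ca_x[ia], ca_y[ia], ca_z[ia]
                        for ib in range(nb):
                            j1, l1, n1 = cb_x[ib], cb_y[ib], cb_z[ib]
                            for ic in range(nc):
                                i2, k2, m2 = cc_x[ic], cc_y[ic], cc_z[ic]
                                for id_ in range(nd):
                                    j2, l2, n2 = (cd_x[id_], cd_y[id_],
                                                  cd_z[id_])
                                    v = 0.0
                                    for t in range(i1 + j1 + 1):
                                        for u in range(k1 + l1 + 1):
                                            for w in range(m1 + n1 + 1):
                                                e1 = (e1x[i1, j1, t]
                                                      * e1y[k1, l1, u]
                                                      * e1z[m1, n1, w])
                                                if e1 == 0.0:
                                                    continue
                                                for t2 in range(i2 + j2 + 1):
                                                    for u2 in range(
                                                            k2 + l2 + 1):
                                                        for w2 in range(
                                                                m2 + n2 + 1):
                                                            sgn = 1.0
                                                            if (t2 + u2 + w2) \
                                                                    % 2:
                                                                sgn = -1.0
                                                            v += (sgn * e1
                                                                  * e2x[i2, j2, t2]
                                                                  * e2y[k2, l2, u2]
                                                                  * e2z[m2, n2, w2]
                                                                  * r[t + t2,
                                                                      u + u2,
                                                                      w + w2])
                                    out[ia, ib, ic, id_] += (
                                        pref * v * fa[ia] * fb[ib]
                                        * fc[ic] * fd[id_])


def _shell_arrays(shell: Shell):
    comps = cartesian_components(shell.l)
    cx = np.array([c[0] for c in comps], dtype=np.int64)
    cy = np.array([c[1] for c in comps], dtype=np.int64)
    cz = np.array([c[2] for c in comps], dtype=np.int64)
    f = component_factors(shell.l)
    coefs = shell.coefs * np.array([prim_norm(a, shell.l)
                                    for a in shell.exps])
    return cx, cy, cz, f, coefs


def _offsets(shells):
    off = [0]
    for sh in shells:
        off.append(off[-1] + sh.n_comp)
    return off


def overlap(shells):
    return _one_electron(shells, kind="s")


def kinetic(shells):
    return _one_electron(shells, kind="t")


def _one_electron(shells, kind):
    off = _offsets(shells)
    nbf = off[-1]
    S = np.zeros((nbf, nbf))
    T = np.zeros((nbf, nbf))
    for i, sa in enumerate(shells):
        cax, cay, caz, fa, ca = _shell_arrays(sa)
        for j, sb in enumerate(shells):
            if j > i:
                continue
            cbx, cby, cbz, fb, cb = _shell_arrays(sb)
            s_blk = np.zeros((sa.n_comp, sb.n_comp))
            t_blk = np.zeros((sa.n_comp, sb.n_comp))
            _pair_sk(sa.l, sb.l, sa.center, sb.center, sa.exps, ca,
                     sb.exps, cb, cax, cay, caz, cbx, cby, cbz, fa, fb,
                     s_blk, t_blk)
            S[off[i]:off[i + 1], off[j]:off[j + 1]] = s_blk
            S[off[j]:off[j + 1], off[i]:off[i + 1]] = s_blk.T
            T[off[i]:off[i + 1], off[j]:off[j + 1]] = t_blk
            T[off[j]:off[j + 1], off[i]:off[i + 1]] = t_blk.T
    return S if kind == "s" else T


def nuclear(shells, charges, coords):
    off = _offsets(shells)
    nbf = off[-1]
    V = np.zeros((nbf, nbf))
    zs = np.asarray(charges, float)
    coords = np.asarray(coords, float)
    for i, sa in enumerate(shells):
        cax, cay, caz, fa, ca = _shell_arrays(sa)
        for j, sb in enumerate(shells):
            if j > i:
                continue
            cbx, cby, cbz, fb, cb = _shell_arrays(sb)
            blk = np.zeros((sa.n_comp, sb.n_comp))
            _pair_nuc(sa.l, sb.l, sa.center, sb.center, sa.exps, ca,
                      sb.exps, cb, cax, cay, caz, cbx, cby, cbz, fa, fb,
                      zs, coords, blk)
            V[off[i]:off[i + 1], off[j]:off[j + 1]] = blk
            V[off[j]:off[j + 1], off[i]:off[i + 1]] = blk.T
    return V


def eri(shells):
    """Full (pq|rs) tensor over AO basis functions."""
    off = _offsets(shells)
    nbf = off[-1]
    G = np.zeros((nbf, nbf, nbf, nbf))
    arrays = [_shell_arrays(sh) for sh in shells]
    ns = len(shells)
    for i in range(ns):
        for j in range(i + 1):
            for k in range(ns):
                for l in range(k + 1):
                    if (i, j) < (k, l):
                        continue
                    sa, sb, sc, sd = shells[i], shells[j], shells[k], \
                        shells[l]
                    cax, cay, caz, fa, ca = arrays[i]
                    cbx, cby, cbz, fb, cb = arrays[j]
                    ccx, ccy, ccz, fc, cc = arrays[k]
                    cdx, cdy, cdz, fd, cd = arrays[l]
                    blk = np.zeros((sa.n_comp, sb.n_comp, sc.n_comp,
                                    sd.n_comp))
                    _quartet_eri(sa.l, sb.l, sc.l, sd.l, sa.center,
                                 sb.center, sc.center, sd.center,
                                 sa.exps, ca, sb.exps, cb, sc.exps, cc,
                                 sd.exps, cd,
                                 cax, cay, caz, cbx, cby, cbz,
                                 ccx, ccy, ccz, cdx, cdy, cdz,
                                 fa, fb, fc, fd, blk)
                    oi, oj = off[i], off[j]
                    ok, ol = off[k], off[l]
                    for a in range(sa.n_comp):
                        for b in range(sb.n_comp):
                            for c in range(sc.n_comp):
                                for d in range(sd.n_comp):
                                    v = blk[a, b, c, d]
                                    pi, qj = oi + a, oj + b
                                    rk, sl = ok + c, ol + d
                                    G[pi, qj, rk, sl] = v
                                    G[qj, pi, rk, sl] = v
                                    G[pi, qj, sl, rk] = v
                                    G[qj, pi, sl, rk] = v
                                    G[rk, sl, pi, qj] = v
                                    G[sl, rk, pi, qj] = v
                                    G[rk, sl, qj, pi] = v
                                    G[sl, rk, qj, pi] = v
    return G


def ao_integrals(shells, charges, coords):
    """(S, hcore, eri) over the AO basis."""
    S = overlap(shells)
    h = kinetic(shells) + nuclear(shells, charges, coords)
    return S, h, eri(shells)
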