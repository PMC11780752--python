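"""Determinant CI machinery in fixed (n_orb, n_alpha, n_beta) sectors.

Conventions
-----------
A determinant of a sector is ``a+_{p1,a} ... a+_{pk,a} a+_{q1,b} ... |vac>``
with alpha creation operators first, each group in ascending orbital order.
Sector basis states are indexed ``i = i_alpha * N_beta + i_beta`` over the
lexicographically sorted occupation bitmasks of each spin.

All fermionic phases follow from this ordering.  A beta-spin elementary
operator therefore picks up a global sign ``(-1)**n_alpha`` for crossing the
alpha block; spin-conserving one-body beta operators cross it twice and get
no sign.

Operators are represented as tuples of *factors*, applied right-to-left:

``("cre", p, s)`` / ``("ann", p, s)``
    elementary creation/annihilation on orbital ``p``, spin ``s`` (0=alpha).
``("E", p, q)`` spin-summed excitation ``E_pq``.
``("dE", p, q, mean)`` fluctuation ``E_pq - mean``.
``("Sz", p, q)`` spin-polarization ``(a+_pa a_qa - a+_pb a_qb)/2``.
``("dSz", p, q, mean)`` its fluctuation.
``("S+", p, q)`` = ``a+_pa a_qb``;  ``("S-", p, q)`` = ``a+_pb a_qa``.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Sector", "strings", "sector_dim", "apply_factor", "apply_ops",
    "sector_hamiltonian", "solve_sector", "SectorWavefunction",
    "rdm1_spin", "rdm_spinfree", "davidson",
]


@lru_cache(maxsize=None)
def strings(n_orb: int, k: int) -> np.ndarray:
    """Sorted occupation bitmasks of k electrons in n_orb orbitals."""
    if k < 0 or k > n_orb:
        return np.empty(0, dtype=np.int64)
    out = []
    for occ in combinations(range(n_orb), k):
        m = 0
        for p in occ:
            m |= 1 << p
        out.append(m)
    return np.array(sorted(out), dtype=np.int64)


@lru_cache(maxsize=None)
def _string_index(n_orb: int, k: int):
    return {int(s): i for i, s in enumerate(strings(n_orb, k))}


def sector_dim(n_orb: int, na: int, nb: int) -> int:
    from math import comb
    if na < 0 or nb < 0 or na > n_orb or nb > n_orb:
        return 0
    return comb(n_orb, na) * comb(n_orb, nb)


def _parity_below(mask: int, p: int) -> int:
    """(-1)**(number of set bits in mask strictly below position p)."""
    return 1 - 2 * (bin(mask & ((1 << p) - 1)).count("1") & 1)


@lru_cache(maxsize=None)
def cre_matrix(n_orb: int, k: int, p: int) -> sp.csr_matrix:
    """a+_p : strings(k) -> strings(k+1), with sign, as a sparse matrix."""
    src = strings(n_orb, k)
    dst_index = _string_index(n_orb, k + 1)
    rows, cols, vals = [], [], []
    bit = 1 << p
    for i, s in enumerate(src):
        s = int(s)
        if s & bit:
            continue
        rows.append(dst_index[s | bit])
        cols.append(i)
        vals.append(_parity_below(s, p))
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(len(dst_index), len(src)), dtype=float)


@lru_cache(maxsize=None)
def ann_matrix(n_orb: int, k: int, p: int) -> sp.csr_matrix:
    """a_p : strings(k) -> strings(k-1), with sign."""
    return cre_matrix(n_orb, k - 1, p).T.tocsr()


@lru_cache(maxsize=None)
def exc_matrix(n_orb: int, k: int, p: int, q: int) -> sp.csr_matrix:
    """a+_p a_q within strings(k), with sign."""
    src = strings(n_orb, k)
    idx = _string_index(n_orb, k)
    rows, cols, vals = [], [], []
    bp, bq = 1 << p, 1 << q
    for i, s in enumerate(src):
        s = int(s)
        if not s & bq:
            continue
        t = s & ~bq
        sgn = _parity_below(s, q)
        if t & bp:
            continue
        sgn *= _parity_below(t, p)
        rows.append(idx[t | bp])
        cols.append(i)
        vals.append(sgn)
    return sp.csr_matrix((vals, (rows, cols)),
                         shape=(len(src), len(src)), dtype=float)


class Sector:
    """A fixed (n_orb, n_alpha, n_beta) determinant space."""

    def __init__(self, n_orb: int, na: int, nb: int):
        if not (0 <= na <= n_orb and 0 <= nb <= n_orb):
            raise ValueError(f"empty sector ({n_orb},{na},{nb})")
        self.n_orb = n_orb
        self.na = na
        self.nb = nb
        self.str_a = strings(n_orb, na)
        self.str_b = strings(n_orb, nb)
        self.dim_a = len(self.str_a)
        self.dim_b = len(self.str_b)
        self.dim = self.dim_a * self.dim_b

    @property
    def key(self):
        return (self.n_orb, self.na, self.nb)

    def __eq__(self, other):
        return isinstance(other, Sector) and self.key == other.key

    def __hash__(self):
        return hash(self.key)

    def __repr__(self):
        return f"Sector{self.key}"


@lru_cache(maxsize=None)
def get_sector(n_orb: int, na: int, nb: int) -> Sector:
    return Sector(n_orb, na, nb)


def _as2d(vec, sector: Sector):
    return np.asarray(vec).reshape(sector.dim_a, sector.dim_b)


def apply_factor(vec: np.ndarray, sector: Sector, factor):
    """Apply one operator factor; returns (new_vec, new_sector) or None.

    ``None`` signals the target sector does not exist (annihilated state).
    """
    n = sector.n_orb
    na, nb = sector.na, sector.nb
    kind = factor[0]
    v = _as2d(vec, sector)

    if kind in ("cre", "ann"):
        _, p, s = factor
        dn = 1 if kind == "cre" else -1
        if s == 0:
            k2 = na + dn
            if k2 < 0 or k2 > n:
                return None
            m = cre_matrix(n, na, p) if kind == "cre" else ann_matrix(n, na, p)
            out = m @ v
            tgt = get_sector(n, k2, nb)
        else:
            k2 = nb + dn
            if k2 < 0 or k2 > n:
                return None
            m = cre_matrix(n, nb, p) if kind == "cre" else ann_matrix(n, nb, p)
            out = (v @ m.T) * (1.0 if na % 2 == 0 else -1.0)
            tgt = get_sector(n, na, k2)
        return out.ravel(), tgt

    if kind in ("E", "dE"):
        p, q = factor[1], factor[2]
        out = exc_matrix(n, na, p, q) @ v + v @ exc_matrix(n, nb, p, q).T
        if kind == "dE":
            out = out - factor[3] * v
        return out.ravel(), sector

    if kind in ("Sz", "dSz"):
        p, q = factor[1], factor[2]
        out = 0.5 * (exc_matrix(n, na, p, q) @ v
                     - v @ exc_matrix(n, nb, p, q).T)
        if kind == "dSz":
            out = out - factor[3] * v
        return out.ravel(), sector

    if kind == "S+":          # a+_pa a_qb
        p, q = factor[1], factor[2]
        res = apply_factor(vec, sector, ("ann", q, 1))
        if res is None:
            return None
        tmp, sec2 = res
        return apply_factor(tmp, sec2, ("cre", p, 0))

    if kind == "S-":          # a+_pb a_qa
        p, q = factor[1], factor[2]
        res = apply_factor(vec, sector, ("ann", q, 0))
        if res is None:
            return None
        tmp, sec2 = res
        return apply_factor(tmp, sec2, ("cre", p, 1))

    raise ValueError(f"unknown factor {factor!r}")


def apply_ops(vec: np.ndarray, sector: Sector, ops):
    """Apply a tuple of factors right-to-left. Returns (vec, sector) or None."""
    cur, sec = np.asarray(vec, dtype=float), sector
    for factor in reversed(ops):
        res = apply_factor(cur, sec, factor)
        if res is None:
            return None
        cur, sec = res
    return cur, sec


def ops_delta(ops) -> tuple:
    """(dN, 2*dSz) induced by an operator factor tuple."""
    dn = 0
    dm = 0
    for f in ops:
        if f[0] == "cre":
            dn += 1
            dm += 1 if f[2] == 0 else -1
        elif f[0] == "ann":
            dn -= 1
            dm -= 1 if f[2] == 0 else -1
        elif f[0] == "S+":
            dm += 2
        elif f[0] == "S-":
            dm -= 2
    return dn, dm


def ops_n_elementary(ops) -> int:
    """Number of elementary fermionic operators in a factor tuple."""
    n = 0
    for f in ops:
        n += 1 if f[0] in ("cre", "ann") else 2
    return n


# ---------------------------------------------------------------------------
# Sector Hamiltonians


@lru_cache(maxsize=8)
def _dense_e_table(key) -> np.ndarray:
    """All spin-summed E_pq as dense matrices, shape (n, n, dim, dim)."""
    sector = get_sector(*key)
    n, dim = sector.n_orb, sector.dim
    out = np.zeros((n, n, dim, dim))
    ia = sp.identity(sector.dim_a, format="csr")
    ib = sp.identity(sector.dim_b, format="csr")
    for p in range(n):
        for q in range(n):
            m = (sp.kron(exc_matrix(n, sector.na, p, q), ib)
                 + sp.kron(ia, exc_matrix(n, sector.nb, p, q)))
            out[p, q] = m.toarray()
    return out


def sector_e_op(sector: Sector, p: int, q: int) -> sp.csr_matrix:
    """Sparse spin-summed E_pq in a sector."""
    n = sector.n_orb
    a = sp.kron(exc_matrix(n, sector.na, p, q),
                sp.identity(sector.dim_b, format="csr"), format="csr")
    b = sp.kron(sp.identity(sector.dim_a, format="csr"),
                exc_matrix(n, sector.nb, p, q), format="csr")
    return (a + b).tocsr()


def sector_one_body(m: np.ndarray, sector: Sector, dense_cap: int = 1600):
    """Matrix of sum_pq m[p,q] E_pq in a sector."""
    n = sector.n_orb
    if sector.dim <= dense_cap:
        et = _dense_e_table(sector.key)
        return np.tensordot(m, et, axes=2)
    H = None
    for p in range(n):
        for q in range(n):
            if abs(m[p, q]) > 1e-15:
                t = m[p, q] * sector_e_op(sector, p, q)
                H = t if H is None else H + t
    if H is None:
        H = sp.csr_matrix((sector.dim, sector.dim))
    return H.tocsr()


def sector_one_body_spin(ma: np.ndarray, mb: np.ndarray, sector: Sector):
    """Matrix of sum_pq ma[p,q] a+_pa a_qa + mb[p,q] a+_pb a_qb (CSR)."""
    n = sector.n_orb
    oa = None
    ob = None
    for p in range(n):
        for q in range(n):
            if abs(ma[p, q]) > 1e-15:
                t = ma[p, q] * exc_matrix(n, sector.na, p, q)
                oa = t if oa is None else oa + t
            if abs(mb[p, q]) > 1e-15:
                t = mb[p, q] * exc_matrix(n, sector.nb, p, q)
                ob = t if ob is None else ob + t
    ia = sp.identity(sector.dim_a, format="csr")
    ib = sp.identity(sector.dim_b, format="csr")
    out = sp.csr_matrix((sector.dim, sector.dim))
    if oa is not None:
        out = out + sp.kron(oa, ib, format="csr")
    if ob is not None:
        out = out + sp.kron(ia, ob, format="csr")
    return out.tocsr()


def factor_matrix(factor, sector: Sector):
    """Sparse matrix of one operator factor; returns (matrix, target_sector).

    ``None`` if the target sector is outside Fock space.  Results are cached;
    treat the returned matrices as immutable.
    """
    key = (factor, sector.key)
    hit = _factor_cache.get(key)
    if hit is not None or key in _factor_cache:
        return hit
    res = _factor_matrix_impl(factor, sector)
    if len(_factor_cache) > 300_000:
        _factor_cache.clear()
    _factor_cache[key] = res
    return res


_factor_cache: dict = {}


def _factor_matrix_impl(factor, sector: Sector):
    n, na, nb = sector.n_orb, sector.na, sector.nb
    kind = factor[0]
    ia = sp.identity(sector.dim_a, format="csr")
    ib = sp.identity(sector.dim_b, format="csr")
    if kind in ("cre", "ann"):
        _, p, s = factor
        dn = 1 if kind == "cre" else -1
        if s == 0:
            if not 0 <= na + dn <= n:
                return None
            m = cre_matrix(n, na, p) if kind == "cre" else ann_matrix(n, na, p)
            return (sp.kron(m, ib, format="csr"), get_sector(n, na + dn, nb))
        if not 0 <= nb + dn <= n:
            return None
        m = cre_matrix(n, nb, p) if kind == "cre" else ann_matrix(n, nb, p)
        sgn = 1.0 if na % 2 == 0 else -1.0
        return (sgn * sp.kron(ia, m, format="csr"),
                get_sector(n, na, nb + dn))
    if kind in ("E", "dE"):
        p, q = factor[1], factor[2]
        m = (sp.kron(exc_matrix(n, na, p, q), ib, format="csr")
             + sp.kron(ia, exc_matrix(n, nb, p, q), format="csr"))
        if kind == "dE":
            m = m - factor[3] * sp.identity(sector.dim, format="csr")
        return m.tocsr(), sector
    if kind in ("Sz", "dSz"):
        p, q = factor[1], factor[2]
        m = 0.5 * (sp.kron(exc_matrix(n, na, p, q), ib, format="csr")
                   - sp.kron(ia, exc_matrix(n, nb, p, q), format="csr"))
        if kind == "dSz":
            m = m - factor[3] * sp.identity(sector.dim, format="csr")
        return m.tocsr(), sector
    if kind == "S+":
        res = factor_matrix(("ann", factor[2], 1), sector)
        if res is None:
            return None
        m1, s1 = res
        res = factor_matrix(("cre", factor[1], 0), s1)
        if res is None:
            return None
        m2, s2 = res
        return (m2 @ m1).tocsr(), s2
    if kind == "S-":
        res = factor_matrix(("ann", factor[2], 0), sector)
        if res is None:
            return None
        m1, s1 = res
        res = factor_matrix(("cre", factor[1], 1), s1)
        if res is None:
            return None
        m2, s2 = res
        return (m2 @ m1).tocsr(), s2
    raise ValueError(f"unknown factor {factor!r}")


def ops_matrix(ops, sector: Sector):
    """Sparse matrix of a factor tuple on a sector -> (matrix, target_sector).

    ``None`` if any intermediate sector leaves Fock space.  Cached; treat the
    returned matrices as immutable.
    """
    key = (ops, sector.key)
    hit = _ops_cache.get(key)
    if hit is not None or key in _ops_cache:
        return hit
    res = _ops_matrix_impl(ops, sector)
    if len(_ops_cache) > 150_000:
        _ops_cache.clear()
    _ops_cache[key] = res
    return res


_ops_cache: dict = {}


def _ops_matrix_impl(ops, sector: Sector):
    mat = None
    sec = sector
    for factor in reversed(ops):
        res = factor_matrix(factor, sec)
        if res is None:
            return None
        m, sec = res
        mat = m if mat is None else (m @ mat).tocsr()
    if mat is None:
        mat = sp.identity(sector.dim, format="csr")
    return mat, sec


_twobody_cache: dict = {}


def sector_two_body(g: np.ndarray, sector: Sector, dense_cap: int = 1600):
    """Matrix of 1/2 sum_pqrs g (E_pq E_rs - delta_qr E_ps), cached."""
    key = (hash(g.tobytes()), sector.key)
    hit = _twobody_cache.get(key)
    if hit is not None:
        return hit
    n = sector.n_orb
    h1c = -0.5 * np.einsum("prrq->pq", g)
    if sector.dim <= dense_cap:
        et = _dense_e_table(sector.key)
        H = np.tensordot(h1c, et, axes=2)
        gm = g.reshape(n * n, n * n)
        ef = et.reshape(n * n, sector.dim, sector.dim)
        for k in range(n * n):
            col = gm[:, k]
            if np.abs(col).max() < 1e-15:
                continue
            w = np.tensordot(col, ef, axes=1)
            H += 0.5 * (w @ ef[k])
    else:
        H = sector_one_body(h1c, sector, dense_cap=0)
        for r in range(n):
            for s in range(n):
                if np.abs(g[:, :, r, s]).max() < 1e-15:
                    continue
                w = sector_one_body(g[:, :, r, s], sector, dense_cap=0)
                H = H + 0.5 * (w @ sector_e_op(sector, r, s))
        H = H.tocsr()
    if len(_twobody_cache) > 12:
        _twobody_cache.clear()
    _twobody_cache[key] = H
    return H


def sector_hamiltonian(h: np.ndarray, g: np.ndarray, sector: Sector,
                       dense_cap: int = 1600):
    """Matrix of H = sum h E + 1/2 sum g (E E - delta E) in a sector.

    Dense ndarray for small sectors, CSR otherwise.  The two-body part is
    cached across calls with the same integrals (the embedding loop only
    changes the one-body part).
    """
    h1 = sector_one_body(h, sector, dense_cap)
    h2 = sector_two_body(g, sector, dense_cap)
    if sp.issparse(h1) or sp.issparse(h2):
        return (sp.csr_matrix(h1) + sp.csr_matrix(h2)).tocsr()
    return h1 + h2


def hamiltonian_diagonal(h: np.ndarray, g: np.ndarray,
                         sector: Sector) -> np.ndarray:
    """Diagonal <D|H|D> over a sector (for preconditioning)."""
    n = sector.n_orb
    occ_a = ((sector.str_a[:, None] >> np.arange(n)) & 1).astype(float)
    occ_b = ((sector.str_b[:, None] >> np.arange(n)) & 1).astype(float)
    hd = np.diag(h)
    jmat = np.einsum("ppqq->pq", g)
    kmat = np.einsum("pqqp->pq", g)
    ea = occ_a @ hd
    eb = occ_b @ hd
    # coulomb between all pairs, exchange within same spin
    na_, nb_ = occ_a, occ_b
    j_aa = 0.5 * np.einsum("ip,pq,iq->i", na_, jmat, na_)
    j_bb = 0.5 * np.einsum("ip,pq,iq->i", nb_, jmat, nb_)
    j_ab = np.einsum("ip,pq,jq->ij", na_, jmat, nb_)
    k_aa = 0.5 * np.einsum("ip,pq,iq->i", na_, kmat, na_)
    k_bb = 0.5 * np.einsum("ip,pq,iq->i", nb_, kmat, nb_)
    diag = (ea[:, None] + eb[None, :] + j_aa[:, None] + j_bb[None, :]
            + j_ab - k_aa[:, None] - k_bb[None, :])
    return diag.ravel()


def davidson(matvec, diag, dim, n_roots=1, tol=1e-9, max_iter=120,
             max_space=24, v0=None):
    """Davidson eigensolver for the lowest eigenpairs of a symmetric operator.

    Deterministic: the start vector is the unit vector on the lowest diagonal
    entry unless ``v0`` is given.
    """
    if v0 is None:
        i0 = int(np.argmin(diag))
        v0 = np.zeros(dim)
        v0[i0] = 1.0
    V = [v0 / np.linalg.norm(v0)]
    W = []
    theta = None
    for _ in range(max_iter):
        while len(W) < len(V):
            W.append(matvec(V[len(W)]))
        Vm = np.array(V)
        Wm = np.array(W)
        Hs = Vm @ Wm.T
        Hs = 0.5 * (Hs + Hs.T)
        evals, evecs = np.linalg.eigh(Hs)
        theta = evals[:n_roots]
        X = evecs[:, :n_roots]
        ritz = X.T @ Vm
        ritz_w = X.T @ Wm
        resid = ritz_w - theta[:, None] * ritz
        rnorm = np.linalg.norm(resid, axis=1)
        if rnorm.max() < tol:
            return theta, ritz
        if len(V) + n_roots > max_space:
            # thick restart: keep the lowest Ritz vectors (orthonormal since
            # the subspace is); their images are rotated, not recomputed
            keep = min(max(n_roots + 3, 4), len(V))
            Xk = evecs[:, :keep]
            V = list(Xk.T @ Vm)
            W = list(Xk.T @ Wm)
            continue
        for k in range(n_roots):
            if rnorm[k] < 0.1 * tol:
                continue
            denom = diag - theta[k]
            denom = np.where(np.abs(denom) < 1e-8,
                             np.sign(denom + 1e-30) * 1e-8, denom)
            t = resid[k] / denom
            for v in V:
                t -= (v @ t) * v
            nt = np.linalg.norm(t)
            if nt > 1e-10:
                V.append(t / nt)
    return theta, ritz  # pragma: no cover - convergence failure path


class ResourceError(RuntimeError):
    pass


def solve_sector(h, g, sector: Sector, e_shift=0.0, n_roots=1,
                 dim_cap=1_000_000, dense_cap=2500):
    """Exact lowest eigenstate(s) of a sector Hamiltonian.

    Returns (energies + e_shift, vectors) with a deterministic phase: the
    first basis determinant with |c| > 1e-8 has positive coefficient.
    """
    if sector.dim > dim_cap:
        raise ResourceError(f"sector dim {sector.dim} exceeds cap {dim_cap}")
    if sector.dim == 0:
        raise ValueError("empty sector")
    if sector.dim == 1:
        vec = np.ones((1, 1))
        H = sector_hamiltonian(h, g, sector)
        e = float(np.asarray(H).reshape(1)[0]) if not sp.issparse(H) \
            else float(H.toarray()[0, 0])
        return np.array([e + e_shift] * min(n_roots, 1)), vec
    if sector.dim <= dense_cap:
        H = sector_hamiltonian(h, g, sector)
        if sp.issparse(H):
            H = H.toarray()
        evals, evecs = np.linalg.eigh(H)
        vecs = evecs[:, :n_roots].T.copy()
    else:
        H = sector_hamiltonian(h, g, sector, dense_cap=0)
        diag = hamiltonian_diagonal(h, g, sector)
        evals, vecs = davidson(lambda x: H @ x, diag, sector.dim,
                               n_roots=n_roots)
    out = []
    for k in range(n_roots):
        v = vecs[k]
        idx = np.nonzero(np.abs(v) > 1e-8)[0]
        if len(idx) and v[idx[0]] < 0:
            v = -v
        out.append(v / np.linalg.norm(v))
    return np.asarray(evals[:n_roots]) + e_shift, np.array(out)


# ---------------------------------------------------------------------------
# Wavefunction container and RDMs


class SectorWavefunction:
    """A normalized CI vector in one fragment sector, with RDM accessors."""

    def __init__(self, fragment: str, sector: Sector, ci: np.ndarray,
                 energy: float):
        ci = np.asarray(ci, dtype=float).ravel()
        if abs(np.linalg.norm(ci) - 1.0) > 1e-12:
            raise ValueError("CI vector not normalized")
        self.fragment = fragment
        self.sector = sector
        self.ci = ci
        self.energy = float(energy)

    @property
    def n_elec(self):
        return self.sector.na + self.sector.nb

    def rdm1_spin(self):
        return rdm1_spin(self.ci, self.sector)

    def rdm1(self):
        ga, gb = self.rdm1_spin()
        return ga + gb

    def rdm_spinfree(self, order: int):
        return rdm_spinfree(self.ci, self.sector, order)

    def expectation(self, ops) -> float:
        res = apply_ops(self.ci, self.sector, ops)
        if res is None or res[1] != self.sector:
            return 0.0
        return float(self.ci @ res[0])


def transition_moment(bra: "SectorWavefunction", ket: "SectorWavefunction",
                      ops) -> float:
    """<bra| ops |ket> between sector wavefunctions (possibly different
    charge/Sz sectors); zero when the operator does not connect them."""
    res = apply_ops(ket.ci, ket.sector, ops)
    if res is None or res[1] != bra.sector:
        return 0.0
    return float(bra.ci @ res[0])


def transition_rdm1(bra: "SectorWavefunction",
                    ket: "SectorWavefunction") -> np.ndarray:
    """Spin-summed transition 1-RDM <bra|E_pq|ket> (sectors must match in
    particle number and Sz; otherwise identically zero)."""
    n = ket.sector.n_orb
    out = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            out[p, q] = transition_moment(bra, ket, (("E", p, q),))
    return out


def rdm1_spin(vec, sector: Sector):
    """Spin-resolved 1-RDMs gamma^s_pq = <a+_ps a_qs>."""
    n = sector.n_orb
    v = _as2d(vec, sector)
    ga = np.zeros((n, n))
    gb = np.zeros((n, n))
    for p in range(n):
        for q in range(n):
            ga[p, q] = np.vdot(v, exc_matrix(n, sector.na, p, q) @ v)
            gb[p, q] = np.vdot(v, v @ exc_matrix(n, sector.nb, p, q).T)
    return ga, gb


def rdm_spinfree(vec, sector: Sector, order: int):
    """Spin-free product RDMs <E_{p1 q1} ... E_{pk qk}>, k = order <= 4.

    Index layout: tensor[p1, q1, p2, q2, ...].  For ``order == 2`` the
    conventional 2-RDM is ``<E E> - delta <E>`` (see
    :func:`contracted_energy`); this function returns the raw product
    expectation values from which such forms are assembled.
    """
    if not 1 <= order <= 4:
        raise ResourceError("rdm order must be in 1..4")
    n = sector.n_orb
    vec = np.asarray(vec, float).ravel()

    def e_apply_all(mat):
        """Apply all E_pq to each column of mat -> (n*n, m, dim)."""
        cols = mat.reshape(-1, sector.dim)
        out = np.empty((n * n, cols.shape[0], sector.dim))
        for p in range(n):
            for q in range(n):
                for j, c in enumerate(cols):
                    r, _ = apply_ops(c, sector, (("E", p, q),))
                    out[p * n + q, j] = r
        return out

    base = vec[None, :]
    layers = [base]
    for _ in range((order + 1) // 2):
        prev = layers[-1]
        nxt = e_apply_all(prev).reshape(-1, sector.dim)
        layers.append(nxt)
    k_right = (order + 1) // 2
    k_left = order - k_right
    right = layers[k_right]
    left = layers[k_left]
    # left chain holds E_{i1}..E_{ik_left} |psi>; bra needs its adjoint:
    # <psi| E_{p1 q1}..E_{pl ql} = (E_{ql pl}..E_{q1 p1}|psi>)^T, so transpose
    # each (p,q) pair and reverse the chain order.
    gram = left @ right.T
    shape_l = (n, n) * k_left
    shape_r = (n, n) * k_right
    gram = gram.reshape(shape_l + shape_r)
    # reverse left chain and swap p/q in each left pair
    axes_l = []
    for j in reversed(range(k_left)):
        axes_l.extend([2 * j + 1, 2 * j])
    axes = axes_l + list(range(2 * k_left, 2 * k_left + 2 * k_right))
    return gram.transpose(axes)


def contracted_energy(h, g, e_core, vec, sector: Sector) -> float:
    """<H> via 1- and 2-RDM contraction (energy identity check)."""
    ga, gb = rdm1_spin(vec, sector)
    g1 = ga + gb
    ee = rdm_spinfree(vec, sector, 2)
    d2 = ee - np.einsum("qr,ps->pqrs", np.eye(sector.n_orb), g1)
    return float(e_core + np.einsum("pq,pq->", h, g1)
                 + 0.5 * np.einsum("pqrs,pqrs->", g, d2))
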