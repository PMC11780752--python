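"""Brute-force references: dense combined-space operators, exact CASCI and
uncontracted second-order perturbation theory.

These are pure dense/sparse linear algebra with no code shared with the
factorized perturbation path beyond the type definitions; they serve as
independent oracles in tests and acceptance checks.

The combined determinant space of the dimer keeps the fragment-block
spin-orbital ordering (A-alpha, A-beta, B-alpha, B-beta) so fermionic parity
phases of the factorized machinery can be validated against an elementwise
Slater-Condon construction of the full Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from . import ci
from .decompose import HamiltonianDecomposition, CHANNELS
from .hamiltonian import ActiveSpaceHamiltonian, FragmentPartition

__all__ = ["CombinedBasis", "dense_operator_matrix", "dense_h0",
           "dense_full_hamiltonian", "embed_product", "full_casci",
           "uncontracted_pt2", "OracleResult", "DirectCI"]

DENSE_CAP = 20_000


class CombinedBasis:
    """Union of (sector_A x sector_B) blocks with fixed total (n_alpha, n_beta).

    Block inner index is ``i_A * dim_B + i_B``; blocks are ordered by
    (n_alpha_A, n_beta_A).
    """

    def __init__(self, partition: FragmentPartition, n_alpha: int,
                 n_beta: int):
        self.partition = partition
        self.n_alpha = n_alpha
        self.n_beta = n_beta
        na_orb, nb_orb = partition.n_orb_a, partition.n_orb_b
        self.blocks = []
        self.offsets = {}
        off = 0
        for naa in range(max(0, n_alpha - nb_orb),
                         min(na_orb, n_alpha) + 1):
            for nba in range(max(0, n_beta - nb_orb),
                             min(na_orb, n_beta) + 1):
                sec_a = ci.get_sector(na_orb, naa, nba)
                sec_b = ci.get_sector(nb_orb, n_alpha - naa, n_beta - nba)
                if sec_a.dim == 0 or sec_b.dim == 0:
                    continue
                self.offsets[(naa, nba)] = off
                self.blocks.append((sec_a, sec_b))
                off += sec_a.dim * sec_b.dim
        self.dim = off

    def block_offset(self, sec_a: ci.Sector) -> int:
        return self.offsets[(sec_a.na, sec_a.nb)]

    def iter_blocks(self):
        for (key, off), (sa, sb) in zip(self.offsets.items(), self.blocks):
            yield off, sa, sb

    def bitmask(self, block_idx: int, ia: int, ib: int) -> int:
        """Spin-orbital occupation bitmask of one determinant.

        Bit layout: [A-alpha | A-beta | B-alpha | B-beta] blocks.
        """
        sa, sb = self.blocks[block_idx]
        na, nb = self.partition.n_orb_a, self.partition.n_orb_b
        iaa, iab = divmod(ia, sa.dim_b)
        iba, ibb = divmod(ib, sb.dim_b)
        m = int(sa.str_a[iaa])
        m |= int(sa.str_b[iab]) << na
        m |= int(sb.str_a[iba]) << (2 * na)
        m |= int(sb.str_b[ibb]) << (2 * na + nb)
        return m

    def all_bitmasks(self) -> list:
        out = []
        for bi, (sa, sb) in enumerate(self.blocks):
            for ia in range(sa.dim):
                for ib in range(sb.dim):
                    out.append(self.bitmask(bi, ia, ib))
        return out


def reference_basis(partition: FragmentPartition) -> CombinedBasis:
    return CombinedBasis(partition,
                         partition.n_alpha("A") + partition.n_alpha("B"),
                         partition.n_beta("A") + partition.n_beta("B"))


def _check_dim(basis: CombinedBasis):
    if basis.dim > DENSE_CAP:
        raise ci.ResourceError(
            f"combined space of dim {basis.dim} exceeds {DENSE_CAP}")


def dense_operator_matrix(terms, basis: CombinedBasis) -> np.ndarray:
    """Dense matrix of a list of ChannelTerms on the combined basis."""
    _check_dim(basis)
    H = np.zeros((basis.dim, basis.dim))
    for term in terms:
        n_b_elem = ci.ops_n_elementary(term.ops_b)
        for off, sa, sb in basis.iter_blocks():
            res_a = ci.ops_matrix(term.ops_a, sa)
            res_b = ci.ops_matrix(term.ops_b, sb)
            if res_a is None or res_b is None:
                continue
            ma, ta = res_a
            mb, tb = res_b
            key = (ta.na, ta.nb)
            if key not in basis.offsets:
                continue
            if (ta.na + tb.na != basis.n_alpha
                    or ta.nb + tb.nb != basis.n_beta):
                continue
            off2 = basis.offsets[key]
            phase = 1.0 if ((sa.na + sa.nb) * n_b_elem) % 2 == 0 else -1.0
            blk = (term.coeff * phase) * sp.kron(ma, mb, format="coo")
            H[off2:off2 + blk.shape[0], off:off + blk.shape[1]] += \
                blk.toarray()
    return H


def dense_fragment_part(decomp: HamiltonianDecomposition,
                        basis: CombinedBasis, label: str,
                        effective: bool) -> np.ndarray:
    """Dense kron matrix of H_X (optionally plus its mean-field V_X)."""
    _check_dim(basis)
    H = np.zeros((basis.dim, basis.dim))
    h_loc = decomp.h_local(label)
    g_loc = decomp.g_local(label)
    va, vb = (decomp.v_a if label == "A" else decomp.v_b)
    for off, sa, sb in basis.iter_blocks():
        sec = sa if label == "A" else sb
        m = ci.sector_hamiltonian(h_loc, g_loc, sec)
        m = np.asarray(m.toarray() if sp.issparse(m) else m)
        if effective:
            m = m + ci.sector_one_body_spin(va, vb, sec).toarray()
        if label == "A":
            blk = np.kron(m, np.eye(sb.dim))
        else:
            blk = np.kron(np.eye(sa.dim), m)
        H[off:off + blk.shape[0], off:off + blk.shape[1]] += blk
    return H


def dense_h0(decomp: HamiltonianDecomposition,
             basis: CombinedBasis) -> np.ndarray:
    """H0 = H_A + H_B + V_mf - shift + e_core on the combined basis."""
    H = dense_fragment_part(decomp, basis, "A", effective=True)
    H += dense_fragment_part(decomp, basis, "B", effective=True)
    H += (decomp.e_core - decomp.shift) * np.eye(basis.dim)
    return H


def dense_decomposition(decomp: HamiltonianDecomposition,
                        basis: CombinedBasis) -> np.ndarray:
    """Dense H0 + all channels (must reproduce the full Hamiltonian)."""
    H = dense_h0(decomp, basis)
    for name in CHANNELS:
        H += dense_operator_matrix(decomp.channels[name], basis)
    return H


def embed_product(psi_a: ci.SectorWavefunction, psi_b: ci.SectorWavefunction,
                  basis: CombinedBasis) -> np.ndarray:
    """Coefficient vector of |psi_A> x |psi_B> in the combined basis."""
    key = (psi_a.sector.na, psi_a.sector.nb)
    off = basis.offsets[key]
    block = np.kron(psi_a.ci, psi_b.ci)
    out = np.zeros(basis.dim)
    out[off:off + block.size] = block
    return out


# ---------------------------------------------------------------------------
# Independent full-Hamiltonian route: elementwise Slater-Condon


def _spin_orbital_maps(partition: FragmentPartition):
    """orbital and spin of each global spin-orbital bit."""
    na, nb = partition.n_orb_a, partition.n_orb_b
    orbs, spins = [], []
    for p in range(na):
        orbs.append(p)
        spins.append(0)
    for p in range(na):
        orbs.append(p)
        spins.append(1)
    for p in range(nb):
        orbs.append(na + p)
        spins.append(0)
    for p in range(nb):
        orbs.append(na + p)
        spins.append(1)
    return np.array(orbs), np.array(spins)


def _occ_list(mask: int):
    out = []
    p = 0
    while mask:
        if mask & 1:
            out.append(p)
        mask >>= 1
        p += 1
    return out


def _excitation_sign(m1: int, holes, parts) -> float:
    """Sign of aligning det m1 to the det with holes->parts replaced."""
    sign = 1.0
    m = m1
    for h, p in zip(holes, parts):
        lo, hi = (h, p) if h < p else (p, h)
        nbetween = bin(m & (((1 << hi) - 1) ^ ((1 << (lo + 1)) - 1))).count("1")
        if nbetween % 2:
            sign = -sign
        m = m ^ (1 << h) ^ (1 << p)
    return sign


def dense_full_hamiltonian(ham: ActiveSpaceHamiltonian,
                           partition: FragmentPartition,
                           basis: CombinedBasis) -> np.ndarray:
    """Full H on the combined basis via elementwise Slater-Condon rules."""
    _check_dim(basis)
    if basis.dim > 2500:
        raise ci.ResourceError("Slater-Condon dense build capped at 2500")
    masks = basis.all_bitmasks()
    return _sc_matrix(masks, ham, partition) + ham.e_core * np.eye(len(masks))


def full_h_element(ham, partition, mask_i, mask_j) -> float:
    """One Slater-Condon matrix element <D_i|H|D_j> (without e_core)."""
    orbs, spins = _spin_orbital_maps(partition)
    return _sc_element(mask_i, mask_j, ham.h, ham.g, orbs, spins)


def _sc_element(mi, mj, h, g, orbs, spins) -> float:
    diff = mi ^ mj
    ndiff = bin(diff).count("1")
    if ndiff > 4:
        return 0.0

    def so_h(i, j):
        return h[orbs[i], orbs[j]] if spins[i] == spins[j] else 0.0

    def so_v(i, j, k, l):
        """antisymmetrized <ij||kl> from chemists' (ik|jl)."""
        d = 0.0
        if spins[i] == spins[k] and spins[j] == spins[l]:
            d += g[orbs[i], orbs[k], orbs[j], orbs[l]]
        if spins[i] == spins[l] and spins[j] == spins[k]:
            d -= g[orbs[i], orbs[l], orbs[j], orbs[k]]
        return d

    if ndiff == 0:
        occ = _occ_list(mi)
        val = sum(so_h(i, i) for i in occ)
        for a in range(len(occ)):
            for b in range(a + 1, len(occ)):
                val += so_v(occ[a], occ[b], occ[a], occ[b])
        return val
    if ndiff == 2:
        hole = _occ_list(diff & mj)[0]
        part = _occ_list(diff & mi)[0]
        sign = _excitation_sign(mj, [hole], [part])
        occ = _occ_list(mi & mj)
        val = so_h(part, hole)
        for c in occ:
            val += so_v(part, c, hole, c)
        return sign * val
    holes = _occ_list(diff & mj)
    parts = _occ_list(diff & mi)
    sign = _excitation_sign(mj, holes, parts)
    return sign * so_v(parts[0], parts[1], holes[0], holes[1])


def _sc_matrix(masks, ham, partition) -> np.ndarray:
    orbs, spins = _spin_orbital_maps(partition)
    n = len(masks)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1):
            v = _sc_element(masks[i], masks[j], ham.h, ham.g, orbs, spins)
            H[i, j] = H[j, i] = v
    return H


# ---------------------------------------------------------------------------
# Exact CASCI in the combined space (direct CI for large dimensions)


class DirectCI:
    """String-based direct CI with a Davidson solver.

    Works in the standard (all alpha strings) x (all beta strings) basis;
    eigenvalues are ordering-convention independent.
    """

    def __init__(self, h: np.ndarray, g: np.ndarray, n_orb: int,
                 na: int, nb: int):
        self.n = n_orb
        self.sector = ci.get_sector(n_orb, na, nb)
        self.h = h
        self.g2 = g.reshape(n_orb * n_orb, n_orb * n_orb)
        self.h1 = (h - 0.5 * np.einsum("prrq->pq", g)).reshape(-1)
        self.ea = [ci.exc_matrix(n_orb, na, p, q)
                   for p in range(n_orb) for q in range(n_orb)]
        self.ebt = [ci.exc_matrix(n_orb, nb, p, q).T.tocsr()
                    for p in range(n_orb) for q in range(n_orb)]
        self._d = None

    def matvec(self, c: np.ndarray) -> np.ndarray:
        sec = self.sector
        npair = self.n * self.n
        C = c.reshape(sec.dim_a, sec.dim_b)
        if self._d is None:
            self._d = np.empty((npair, sec.dim_a, sec.dim_b))
        D = self._d
        for k in range(npair):
            D[k] = self.ea[k] @ C
            D[k] += C @ self.ebt[k]
        sigma = np.tensordot(self.h1, D, axes=1)
        G = (self.g2 @ D.reshape(npair, -1)).reshape(D.shape)
        for k in range(npair):
            sigma += 0.5 * (self.ea[k] @ G[k])
            sigma += 0.5 * (G[k] @ self.ebt[k])
        return sigma.ravel()

    def solve(self, n_roots=1, tol=1e-9, v0=None):
        diag = ci.hamiltonian_diagonal(self.h,
                                       self.g2.reshape((self.n,) * 4),
                                       self.sector)
        evals, vecs = ci.davidson(self.matvec, diag, self.sector.dim,
                                  n_roots=n_roots, tol=tol, v0=v0)
        self._d = None
        return evals, vecs


def product_guess_vector(psi_a, psi_b, partition: FragmentPartition):
    """Embed |Psi_A> x |Psi_B> into the standard string-CI basis.

    The string-CI determinant ordering is (all alpha, all beta); reordering
    the product-state convention (A-alpha, A-beta, B-alpha, B-beta) moves the
    B-alpha block past the A-beta block, giving a constant sign
    (-1)**(n_beta_A * n_alpha_B).
    """
    na_orb = partition.n_orb_a
    n_orb = partition.n_orb
    sec_a, sec_b = psi_a.sector, psi_b.sector
    na = sec_a.na + sec_b.na
    nb = sec_a.nb + sec_b.nb
    tgt = ci.get_sector(n_orb, na, nb)
    sign = -1.0 if (sec_a.nb * sec_b.na) % 2 else 1.0
    out = np.zeros((tgt.dim_a, tgt.dim_b))
    ca = psi_a.ci.reshape(sec_a.dim_a, sec_a.dim_b)
    cb = psi_b.ci.reshape(sec_b.dim_a, sec_b.dim_b)
    for ia, sa in enumerate(sec_a.str_a):
        for ib, ta in enumerate(sec_b.str_a):
            ka = int(np.searchsorted(tgt.str_a, int(sa) | (int(ta) << na_orb)))
            for ja, sb in enumerate(sec_a.str_b):
                for jb, tb in enumerate(sec_b.str_b):
                    kb = int(np.searchsorted(
                        tgt.str_b, int(sb) | (int(tb) << na_orb)))
                    out[ka, kb] = sign * ca[ia, ja] * cb[ib, jb]
    return out.ravel()


def full_casci(ham: ActiveSpaceHamiltonian, n_elec: int, ms2: int = 0,
               dim_cap: int = 1_500_000, return_vector: bool = False,
               v0=None, tol: float = 1e-8):
    """Lowest eigenvalue of H in the (n_elec, 2Sz=ms2) combined sector."""
    na = (n_elec + ms2) // 2
    nb = (n_elec - ms2) // 2
    sec = ci.get_sector(ham.n_orb, na, nb)
    if sec.dim > dim_cap:
        raise ci.ResourceError(f"CASCI dim {sec.dim} exceeds cap")
    if sec.dim <= 2000:
        evals, vecs = ci.solve_sector(ham.h, ham.g, sec)
        e = evals[0] + ham.e_core
        vec = vecs[0]
    else:
        engine = DirectCI(ham.h, ham.g, ham.n_orb, na, nb)
        evals, vecs = engine.solve(v0=v0, tol=tol)
        e = evals[0] + ham.e_core
        vec = vecs[0] / np.linalg.norm(vecs[0])
    if return_vector:
        return float(e), vec
    return float(e)


def hylleraas_minimum(decomp: HamiltonianDecomposition, psi_a, psi_b,
                      channel: str, metric_threshold: float = 1e-10):
    """Minimum of the Hylleraas functional over the contracted span, densely.

    Builds every |Phi_mn> = O^A_m O^B_n |Psi0> as an explicit combined-space
    vector, assembles S, (H0 - e0) and the right-hand side from dense
    matrices, and minimizes 2 x.V + x.(H0-e0).x by constrained linear
    algebra.  Independent reference for the factorized PT2 solve.
    """
    basis = reference_basis(decomp.partition)
    _check_dim(basis)
    h0 = dense_h0(decomp, basis)
    psi = embed_product(psi_a, psi_b, basis)
    e0 = float(psi @ h0 @ psi)
    terms = decomp.channels[channel]
    cols = []
    for term in terms:
        op = dense_operator_matrix([type(term)(term.ops_a, term.ops_b, 1.0)],
                                   basis)
        cols.append(op @ psi)
    if not cols:
        return 0.0
    X = np.array(cols).T
    hp = dense_operator_matrix(terms, basis)
    V = X.T @ (hp @ psi)
    S = X.T @ X
    A = X.T @ ((h0 - e0 * np.eye(basis.dim)) @ X)
    evals, U = np.linalg.eigh(S)
    if evals[-1] <= 0:
        return 0.0
    keep = evals > metric_threshold * evals[-1]
    Y = U[:, keep] / np.sqrt(evals[keep])
    At = Y.T @ A @ Y
    At = 0.5 * (At + At.T)
    y = np.linalg.solve(At, -(Y.T @ V))
    x = Y @ y
    # value of the Hylleraas functional 2 x.V + x.(H0-e0).x at its minimum
    return float(2 * V @ x + x @ (A @ x))


# ---------------------------------------------------------------------------
# Uncontracted PT2


@dataclass
class OracleResult:
    e_exact: float = None
    e2_uncontracted: dict = None
    first_order_space_dim: int = None


def uncontracted_pt2(decomp: HamiltonianDecomposition, psi_a, psi_b,
                     channels=None, sing_tol=1e-10):
    """Exact (uncontracted) per-channel E2 by dense resolvent computation.

    Solves (H0 - e0) x = -Q H'_c |Psi0> in the orthogonal complement of the
    reference and returns {channel: e2}.  Fails loudly when H0 - e0 is
    near-singular on the complement (intruder states).
    """
    basis = reference_basis(decomp.partition)
    _check_dim(basis)
    h0 = dense_h0(decomp, basis)
    psi = embed_product(psi_a, psi_b, basis)
    e0 = float(psi @ h0 @ psi)
    proj = np.eye(basis.dim) - np.outer(psi, psi)
    A = h0 - e0 * np.eye(basis.dim) + np.outer(psi, psi)
    evals = np.linalg.eigvalsh(proj @ (h0 - e0 * np.eye(basis.dim)) @ proj
                               + np.outer(psi, psi))
    small = np.abs(evals).min()
    if small < sing_tol:
        raise RuntimeError(
            f"(H0 - e0) nearly singular on the complement: lambda_min="
            f"{small:.3e}")
    names = channels if channels is not None else CHANNELS
    out = {}
    dim1 = 0
    for name in names:
        hc = dense_operator_matrix(decomp.channels[name], basis)
        b = hc @ psi
        r = proj @ b
        dim1 = max(dim1, int(np.sum(np.abs(r) > 1e-12)))
        x = np.linalg.solve(A, -r)
        x = proj @ x
        out[name] = float(b @ x)
    return out, e0, dim1
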