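"""Gaussian integral engine and RHF backend against independent oracles."""

import numpy as np
import pytest
from scipy.special import erf

from fragcas import integrals as ig
from fragcas import oracle
from fragcas.basis import Shell, build_basis, prim_norm
from fragcas.hamiltonian import ActiveSpaceHamiltonian, read_fcidump, \
    write_fcidump
from fragcas.scf import Molecule, run_rhf


def f0(t):
    t = max(t, 1e-14)
    return 0.5 * np.sqrt(np.pi / t) * erf(np.sqrt(t))


# closed forms for unnormalized s primitives (independent oracle)
def s_ovlp(a, A, b, B):
    p = a + b
    ab = np.asarray(A) - np.asarray(B)
    return (np.pi / p) ** 1.5 * np.exp(-a * b / p * ab @ ab)


def s_kin(a, A, b, B):
    p = a + b
    ab = np.asarray(A) - np.asarray(B)
    mu = a * b / p
    return mu * (3 - 2 * mu * (ab @ ab)) * s_ovlp(a, A, b, B)


def s_nuc(a, A, b, B, z, C):
    p = a + b
    A, B, C = map(np.asarray, (A, B, C))
    P = (a * A + b * B) / p
    ab = A - B
    return (-z * 2 * np.pi / p * np.exp(-a * b / p * ab @ ab)
            * f0(p * (P - C) @ (P - C)))


def s_eri(a, A, b, B, c, C, d, D):
    A, B, C, D = map(np.asarray, (A, B, C, D))
    p, q = a + b, c + d
    P = (a * A + b * B) / p
    Q = (c * C + d * D) / q
    return (2 * np.pi ** 2.5 / (p * q * np.sqrt(p + q))
            * np.exp(-a * b / p * (A - B) @ (A - B))
            * np.exp(-c * d / q * (C - D) @ (C - D))
            * f0(p * q / (p + q) * (P - Q) @ (P - Q)))


def bare(l, center, alpha):
    """Single-primitive shell with the primitive normalization divided out."""
    return Shell(l, np.array(center, float), np.array([alpha]),
                 np.array([1.0 / prim_norm(alpha, l)]), 0)


def test_s_integrals_match_closed_forms():
    rng = np.random.default_rng(0)
    for _ in range(10):
        a, b, c, d = rng.uniform(0.1, 40, 4)
        A, B, C, D = rng.normal(0, 1.5, (4, 3))
        sh = [bare(0, A, a), bare(0, B, b), bare(0, C, c), bare(0, D, d)]
        assert abs(ig.overlap(sh)[0, 1] - s_ovlp(a, A, b, B)) < 1e-13
        assert abs(ig.kinetic(sh)[0, 1] - s_kin(a, A, b, B)) < 1e-12
        zc = np.array([[0.3, -0.2, 0.5]])
        assert abs(ig.nuclear(sh, [3.0], zc)[0, 1]
                   - s_nuc(a, A, b, B, 3.0, zc[0])) < 1e-12
        assert abs(ig.eri(sh)[0, 1, 2, 3]
                   - s_eri(a, A, b, B, c, C, d, D)) < 1e-13


def test_p_integrals_match_derivative_oracle():
    """p Gaussians are center derivatives of s Gaussians; compare against
    finite differences of the closed-form s integrals."""
    rng = np.random.default_rng(1)
    h = 1e-5

    def numd(f, A, i):
        ap, am = np.array(A, float), np.array(A, float)
        ap[i] += h
        am[i] -= h
        return (f(ap) - f(am)) / (2 * h)

    for _ in range(4):
        a, b = rng.uniform(0.2, 6, 2)
        A, B = rng.normal(0, 1.0, (2, 3))
        sh = [bare(1, A, a), bare(0, B, b)]
        S, T = ig.overlap(sh), ig.kinetic(sh)
        zc = np.array([[0.1, 0.4, -0.3]])
        V = ig.nuclear(sh, [2.0], zc)
        for i in range(3):
            assert abs(S[i, 3] - numd(lambda x: s_ovlp(a, x, b, B), A, i)
                       / (2 * a)) < 1e-9
            assert abs(T[i, 3] - numd(lambda x: s_kin(a, x, b, B), A, i)
                       / (2 * a)) < 1e-8
            assert abs(V[i, 3] - numd(lambda x: s_nuc(a, x, b, B, 2.0,
                                                      zc[0]), A, i)
                       / (2 * a)) < 1e-8


def test_pp_eri_against_double_derivative_oracle():
    rng = np.random.default_rng(2)
    h = 1e-4
    a, b, c, d = rng.uniform(0.3, 4, 4)
    A, B, C, D = rng.normal(0, 1.2, (4, 3))
    sh = [bare(1, A, a), bare(0, B, b), bare(1, C, c), bare(0, D, d)]
    G = ig.eri(sh)
    for i in range(3):
        for k in range(3):
            def inner(Cx):
                def f(Ax):
                    return s_eri(a, Ax, b, B, c, Cx, d, D)
                ap, am = np.array(A), np.array(A)
                ap[i] += h
                am[i] -= h
                return (f(ap) - f(am)) / (2 * h)
            cp, cm = np.array(C), np.array(C)
            cp[k] += h
            cm[k] -= h
            ref = (inner(cp) - inner(cm)) / (2 * h) / (4 * a * c)
            assert abs(G[i, 3, 4 + k, 7] - ref) < 1e-8


def test_eri_permutational_symmetry():
    shells = build_basis(["N", "H"], np.array([[0, 0, 0], [0, 0, 2.0]]),
                         "sto-3g")
    g = ig.eri(shells)
    for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
        assert np.abs(g - g.transpose(perm)).max() < 1e-12


def test_h2_rhf_matches_textbook():
    """H2/STO-3G near equilibrium: the classic closed-shell RHF energy."""
    mol = Molecule.from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 0.7414]])
    res = run_rhf(mol, "sto-3g")
    assert res.e_tot == pytest.approx(-1.1167, abs=2e-4)


def test_rhf_rotation_invariance():
    coords = np.array([[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692],
                       [0.0, -0.7572, -0.4692]])
    res = run_rhf(Molecule.from_angstrom(["O", "H", "H"], coords), "sto-3g")
    rng = np.random.default_rng(7)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    res2 = run_rhf(Molecule.from_angstrom(["O", "H", "H"], coords @ q.T),
                   "sto-3g")
    assert abs(res.e_tot - res2.e_tot) < 1e-8


def test_h2_fci_survives_fcidump_round_trip(tmp_path):
    """Backend integrals written to FCIDUMP and re-read give the same FCI
    energy to 1e-10."""
    mol = Molecule.from_angstrom(["H", "H"], [[0, 0, 0], [0, 0, 0.7414]])
    res = run_rhf(mol, "sto-3g")
    h_mo = res.C.T @ res.hcore @ res.C
    g_mo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", res.eri, res.C, res.C,
                     res.C, res.C, optimize=True)
    ham = ActiveSpaceHamiltonian(2, res.e_nuc, 0.5 * (h_mo + h_mo.T), g_mo)
    e1 = oracle.full_casci(ham, 2, 0)
    path = tmp_path / "h2.fcidump"
    write_fcidump(ham, path, nelec=2, ms2=0)
    e2 = oracle.full_casci(read_fcidump(path), 2, 0)
    assert abs(e1 - e2) < 1e-10
    assert e1 == pytest.approx(-1.1373, abs=2e-4)
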