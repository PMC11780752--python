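"""Channel-resolved PT2 against dense oracles and exact orderings."""

import numpy as np
import pytest

from fragcas import ci, models, oracle
from fragcas.decompose import CHANNELS, decompose_hamiltonian
from fragcas.embedding import self_consistent_product_state
from fragcas.hamiltonian import ActiveSpaceHamiltonian
from fragcas.pt2 import (build_perturbing_basis, first_order_check,
                         pt2_energies, solve_amplitudes)


def test_noninteracting_all_zero():
    spec = models.ModelSpec(2, 2, 2, 2, lam=0.0, seed=0)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
    res = pt2_energies(decomp, ps)
    assert res.e2_total == 0.0
    assert all(res.channels[n].e2 == 0.0 for n in CHANNELS)


def test_dispersion_members_orthogonal_to_reference(seeded_suite):
    """<Psi0 | dE dE Psi0> = 0 by the fluctuation construction."""
    for case in seeded_suite[:5]:
        ps = case["ps"]
        for block in build_perturbing_basis(case["decomp"], ps,
                                            "dispersion"):
            if block.sector_a == ps.psi_a.sector \
                    and block.sector_b == ps.psi_b.sector:
                ova = block.x_a @ ps.psi_a.ci
                ovb = block.x_b @ ps.psi_b.ci
                assert np.abs(ova * ovb).max() < 1e-12


def test_first_order_vanishes_and_matches_dense(seeded_suite):
    for case in seeded_suite[:6]:
        fo = first_order_check(case["decomp"], case["ps"])
        basis = oracle.reference_basis(case["part"])
        psi = oracle.embed_product(case["ps"].psi_a, case["ps"].psi_b, basis)
        for name in CHANNELS:
            hc = oracle.dense_operator_matrix(case["decomp"].channels[name],
                                              basis)
            dense_val = psi @ hc @ psi
            assert abs(fo[name]) < 1e-10
            assert abs(dense_val - fo[name]) < 1e-12


def test_e2_nonpositive_and_total_additive(seeded_suite):
    for case in seeded_suite:
        res = case["res"]
        for name in CHANNELS:
            assert res.channels[name].e2 <= 1e-12
        assert abs(res.e2_total
                   - sum(res.channels[n].e2 for n in CHANNELS)) < 1e-14


def test_contracted_matches_dense_hylleraas_minimum(seeded_suite):
    """Factorized solve equals the dense constrained minimization."""
    for case in seeded_suite[:5]:
        for name in CHANNELS:
            hyl = oracle.hylleraas_minimum(case["decomp"], case["ps"].psi_a,
                                           case["ps"].psi_b, name)
            assert abs(hyl - case["res"].channels[name].e2) < 1e-9


def test_contraction_ordering(seeded_suite):
    """e2_uncontracted <= e2_partially_contracted <= 0 per channel."""
    for case in seeded_suite:
        for name in CHANNELS:
            e_pc = case["res"].channels[name].e2
            e_unc = case["e2_unc"][name]
            assert e_unc - 1e-10 <= e_pc <= 1e-12


def test_lambda_scaling_slope(lambda_scan):
    """|E_exact - e0 - e2_unc| scales at least cubically in the coupling."""
    lams, resid = lambda_scan
    slope = np.polyfit(np.log(lams), np.log(resid), 1)[0]
    assert slope >= 2.5


def test_zero_rhs_gives_zero_amplitudes():
    S = np.eye(3)
    M = np.diag([1.0, 2.0, 3.0])
    C, diag = solve_amplitudes(S, M, np.zeros(3))
    assert np.abs(C).max() == 0.0


def test_duplicate_member_null_space_invariance():
    """A duplicated basis member does not change e2."""
    rng = np.random.default_rng(0)
    m = 4
    X = rng.normal(size=(m, 10))
    S = X @ X.T
    A = rng.normal(size=(10, 10))
    A = A @ A.T + 10 * np.eye(10)
    M = X @ A @ X.T
    g = rng.normal(size=m)
    V = S @ g
    C, _ = solve_amplitudes(S, M, V)
    e2 = C @ V
    # duplicate the last member (exactly singular overlap)
    X2 = np.vstack([X, X[-1]])
    S2 = X2 @ X2.T
    M2 = X2 @ A @ X2.T
    g2 = np.concatenate([g[:-1], [g[-1] / 2], [g[-1] / 2]])
    V2 = S2 @ g2
    C2, diag2 = solve_amplitudes(S2, M2, V2)
    assert abs(C2 @ V2 - e2) < 1e-10
    assert diag2["kept"] == np.linalg.matrix_rank(S2)


def test_uncontracted_matches_finite_difference():
    """Dense resolvent e2 equals the second derivative of the lowest
    eigenvalue of H0 + lam H' at lam = 0 (per channel)."""
    for seed in (0, 3, 9):
        spec = models.ModelSpec(2, 2, 2, 2, lam=0.3, seed=seed)
        ham, part = models.model_hamiltonian(spec)
        ps = self_consistent_product_state(ham, part)
        decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
        e2u, e0, _ = oracle.uncontracted_pt2(decomp, ps.psi_a, ps.psi_b)
        basis = oracle.reference_basis(part)
        h0 = oracle.dense_h0(decomp, basis)
        hp = sum(oracle.dense_operator_matrix(decomp.channels[name], basis)
                 for name in CHANNELS)
        ref = sum(e2u.values())
        de = 1e-3
        es = [np.linalg.eigvalsh(h0 + lam * hp)[0] for lam in (-de, 0.0, de)]
        d2 = (es[0] - 2 * es[1] + es[2]) / de ** 2
        assert abs(d2 / 2 - ref) / abs(ref) < 1e-4


def test_spin_symmetry_pairing_equivalence():
    spec = models.ModelSpec(3, 3, 2, 2, lam=0.25, seed=12)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
    r1 = pt2_energies(decomp, ps, exploit_spin_symmetry=True)
    r2 = pt2_energies(decomp, ps, exploit_spin_symmetry=False)
    for name in CHANNELS:
        assert abs(r1.channels[name].e2 - r2.channels[name].e2) < 1e-12


def test_channel_e2_swap_invariance():
    """Relabeling A <-> B swaps the 1CT directions, leaves e2 unchanged."""
    spec = models.ModelSpec(3, 2, 2, 2, lam=0.2, seed=9)
    ham, part = models.model_hamiltonian(spec)

    def solve(h, p):
        ps = self_consistent_product_state(h, p)
        d = decompose_hamiltonian(h, p, ps.gamma_a, ps.gamma_b)
        return pt2_energies(d, ps)

    res = solve(ham, part)
    perm = list(range(3, 5)) + list(range(3))
    ham2 = ActiveSpaceHamiltonian(5, ham.e_core, ham.h[np.ix_(perm, perm)],
                                  ham.g[np.ix_(perm, perm, perm, perm)])
    res2 = solve(ham2, part.swapped())
    pairing = {"dispersion": "dispersion", "ct1_AtoB": "ct1_BtoA",
               "ct1_BtoA": "ct1_AtoB", "ct2": "ct2", "tt": "tt"}
    for name, other in pairing.items():
        assert abs(res.channels[name].e2 - res2.channels[other].e2) < 1e-10
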