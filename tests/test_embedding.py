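"""Self-consistent product state: exact limits, variational properties."""

import numpy as np
import pytest

from fragcas import ci, models, oracle
from fragcas.embedding import (build_effective_hamiltonian, fci_solve_sector,
                               sector_matrix, self_consistent_product_state)
from fragcas.hamiltonian import ActiveSpaceHamiltonian


def test_noninteracting_additivity():
    """lam = 0: e0 equals the sum of independent fragment FCI energies."""
    spec = models.ModelSpec(3, 2, 2, 2, lam=0.0, seed=0)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    e_a, _ = ci.solve_sector(ham.h[:3, :3], ham.g[:3, :3, :3, :3],
                             ci.get_sector(3, 1, 1))
    e_b, _ = ci.solve_sector(ham.h[3:, 3:], ham.g[3:, 3:, 3:, 3:],
                             ci.get_sector(2, 1, 1))
    assert abs(ps.e0 - (e_a[0] + e_b[0] + ham.e_core)) < 1e-12
    assert len(ps.iteration_log) <= 2


def test_zero_gamma_gives_bare_hamiltonian():
    ham, part = models.model_hamiltonian(models.ModelSpec(2, 2, lam=0.8,
                                                          seed=1))
    zero = (np.zeros((2, 2)), np.zeros((2, 2)))
    (ha, hb), g_loc, shift = build_effective_hamiltonian(ham, part, "A", zero)
    assert np.abs(ha - ham.h[:2, :2]).max() < 1e-14
    assert np.abs(ha - hb).max() < 1e-14


def test_noninteracting_heff_independent_of_gamma():
    ham, part = models.model_hamiltonian(models.ModelSpec(2, 2, lam=0.0,
                                                          seed=2))
    gam = (np.diag([1.0, 0.0]), np.diag([1.0, 0.0]))
    (ha, _), _, _ = build_effective_hamiltonian(ham, part, "A", gam)
    assert np.abs(ha - ham.h[:2, :2]).max() < 1e-14


def test_h0_expectation_identity(seeded_suite):
    """<Psi0|H0|Psi0> computed densely equals the bookkept e0."""
    for case in seeded_suite[:6]:
        basis = oracle.reference_basis(case["part"])
        h0 = oracle.dense_h0(case["decomp"], basis)
        psi = oracle.embed_product(case["ps"].psi_a, case["ps"].psi_b, basis)
        assert abs(psi @ h0 @ psi - case["ps"].e0) < 1e-10


def test_variational_sandwich(seeded_suite):
    """E_exact <= e0 <= product-determinant reference on every model."""
    for case in seeded_suite:
        assert case["e_exact"] <= case["ps"].e0 + 1e-10
        assert case["ps"].e0 <= case["ps"].e_ref + 1e-10


def test_small_coupling_quadratic_error():
    """At lam = 0.05 the embedding misses at most O(lam^2) energy."""
    spec = models.ModelSpec(2, 2, 2, 2, lam=0.05, seed=5)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    e_exact = oracle.full_casci(ham, 4, 0)
    assert 0 <= ps.e0 - e_exact <= 2 * 0.05 ** 2


def test_converged_state_is_effective_eigenvector(seeded_suite):
    """Residual ||(H_eff - E) psi|| < 1e-7 for both fragments."""
    for case in seeded_suite[:8]:
        decomp, ps = case["decomp"], case["ps"]
        for lab, psi in (("A", ps.psi_a), ("B", ps.psi_b)):
            h = sector_matrix(decomp.h_eff_spin(lab), decomp.g_local(lab),
                              psi.sector)
            h = np.asarray(h)
            e = psi.ci @ h @ psi.ci
            assert np.linalg.norm(h @ psi.ci - e * psi.ci) < 1e-7


def test_intrafragment_rotation_invariance():
    """e0 is invariant under orbital rotations within a fragment."""
    spec = models.ModelSpec(3, 3, 2, 2, lam=0.2, seed=7)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    rng = np.random.default_rng(0)
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    u = np.eye(6)
    u[:3, :3] = q
    ham2 = ham.rotated(u)
    ps2 = self_consistent_product_state(ham2, part)
    assert abs(ps.e0 - ps2.e0) < 1e-9


def test_fragment_swap_invariance():
    """Exchanging labels A and B leaves e0 unchanged."""
    spec = models.ModelSpec(3, 2, 2, 2, lam=0.3, seed=8)
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    perm = list(range(3, 5)) + list(range(3))
    ham2 = ActiveSpaceHamiltonian(
        5, ham.e_core, ham.h[np.ix_(perm, perm)],
        ham.g[np.ix_(perm, perm, perm, perm)])
    ps2 = self_consistent_product_state(ham2, part.swapped())
    assert abs(ps.e0 - ps2.e0) < 1e-10


def test_empty_sector_returns_vacuum():
    h = np.zeros((2, 2))
    g = np.zeros((2, 2, 2, 2))
    states = fci_solve_sector(h, g, 0.7, (2, 0, 0))
    assert states[0].energy == pytest.approx(0.7)
    assert states[0].ci.shape == (1,)


def test_dimension_cap_enforced():
    h = np.zeros((6, 6))
    g = np.zeros((6, 6, 6, 6))
    with pytest.raises(ci.ResourceError):
        fci_solve_sector(h, g, 0.0, (6, 3, 3), dim_cap=10)


def test_solver_matches_dense_on_seeded_sector():
    """(6,3,3) seeded sector energy agrees with dense diagonalization."""
    rng = np.random.default_rng(4)
    h = rng.normal(size=(6, 6))
    h = 0.5 * (h + h.T)
    from fragcas.hamiltonian import symmetrize_g
    g = symmetrize_g(0.2 * rng.normal(size=(6,) * 4))
    states = fci_solve_sector(h, g, 0.0, (6, 3, 3))
    hd = ci.sector_hamiltonian(h, g, ci.get_sector(6, 3, 3))
    e_dense = np.linalg.eigvalsh(np.asarray(hd))[0]
    assert abs(states[0].energy - e_dense) < 1e-9
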