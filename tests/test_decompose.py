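"""Hamiltonian decomposition: exactness, channel structure, classification."""

import numpy as np
import pytest

from fragcas import models, oracle
from fragcas.decompose import (CHANNELS, decompose_hamiltonian, mean_field)
from fragcas.embedding import self_consistent_product_state
from fragcas.operators import classify_term, expand_monomials, \
    factorize_monomial


def converged_decomposition(spec):
    ham, part = models.model_hamiltonian(spec)
    ps = self_consistent_product_state(ham, part)
    return ham, part, ps, decompose_hamiltonian(ham, part, ps.gamma_a,
                                                ps.gamma_b)


@pytest.mark.parametrize("spec", [
    models.ModelSpec(2, 2, 2, 2, 0, 0, lam=0.7, seed=0),
    models.ModelSpec(3, 3, 2, 4, 0, 0, lam=0.5, seed=1),
    models.ModelSpec(2, 3, 1, 3, 1, 1, lam=0.9, seed=2),   # open shell
    models.ModelSpec(3, 2, 3, 2, 1, 0, lam=0.3, seed=3),
])
def test_dense_reconstruction_identity(spec):
    """H_A + H_B + V_mf - shift + sum(channels) == H, elementwise."""
    ham, part = models.model_hamiltonian(spec)
    rng = np.random.default_rng(42 + spec.seed)
    gammas = []
    for lab in ("A", "B"):
        n = part.n_orb_frag(lab)
        pair = []
        for ne in (part.n_alpha(lab), part.n_beta(lab)):
            x = rng.normal(size=(n, n))
            w, v = np.linalg.eigh(x @ x.T)
            occ = np.zeros(n)
            occ[:ne] = 1.0
            if 0 < ne < n:
                occ[0] -= 0.15
                occ[-1] += 0.15
            pair.append((v * occ) @ v.T)
        gammas.append(tuple(pair))
    decomp = decompose_hamiltonian(ham, part, gammas[0], gammas[1])
    basis = oracle.reference_basis(part)
    h_full = oracle.dense_full_hamiltonian(ham, part, basis)
    h_rec = oracle.dense_decomposition(decomp, basis)
    assert np.abs(h_full - h_rec).max() < 1e-10


def test_noninteracting_limit_empty_channels():
    spec = models.ModelSpec(2, 2, 2, 2, lam=0.0, seed=4)
    ham, part, ps, decomp = converged_decomposition(spec)
    for name in CHANNELS:
        assert decomp.channels[name] == []
    assert abs(decomp.shift) < 1e-14
    for v in decomp.v_a + decomp.v_b:
        assert np.abs(v).max() < 1e-14


def test_channel_terms_disjoint():
    """No (O_A, O_B) operator pair appears in two channels."""
    spec = models.ModelSpec(3, 3, 2, 2, lam=0.5, seed=6)
    _, _, _, decomp = converged_decomposition(spec)
    seen = {}
    for name in CHANNELS:
        for term in decomp.channels[name]:
            key = (term.ops_a, term.ops_b)
            assert key not in seen, f"{key} in {name} and {seen[key]}"
            seen[key] = name


SECTOR_OFFSETS = {"dispersion": (0, 0), "ct1_BtoA": (1, None),
                  "ct1_AtoB": (-1, None), "ct2": (2, None), "tt": (0, None)}


def test_channel_symmetry_action():
    """Each channel's dense matrix maps sharp (N_A, Sz_A) blocks only to
    blocks with the advertised fragment-charge offset."""
    spec = models.ModelSpec(2, 2, 2, 2, lam=0.5, seed=8)
    _, part, _, decomp = converged_decomposition(spec)
    basis = oracle.reference_basis(part)
    for name in CHANNELS:
        m = oracle.dense_operator_matrix(decomp.channels[name], basis)
        for off_k, (sa_k, sb_k) in zip(basis.offsets.values(), basis.blocks):
            blk = m[:, off_k:off_k + sa_k.dim * sb_k.dim]
            if np.abs(blk).max() < 1e-14:
                continue
            for off_b, (sa_b, sb_b) in zip(basis.offsets.values(),
                                           basis.blocks):
                sub = blk[off_b:off_b + sa_b.dim * sb_b.dim]
                if np.abs(sub).max() < 1e-14:
                    continue
                dn_a = (sa_b.na + sa_b.nb) - (sa_k.na + sa_k.nb)
                want = SECTOR_OFFSETS[name][0]
                if name == "ct2":
                    assert abs(dn_a) == 2
                elif name.startswith("ct1"):
                    assert dn_a == want
                else:
                    assert dn_a == 0


def test_classify_term_examples():
    part = models.ModelSpec(2, 2).partition()
    assert classify_term((0, 1, 1, 0), part) == "intra_A"
    assert classify_term((2, 3, 2, 2), part) == "intra_B"
    assert classify_term((0, 0, 2, 2), part) == "coulomb_like_AB"
    assert classify_term((0, 2, 2, 0), part) == "spin_carrying_AB"
    assert classify_term((0, 2, 3, 3), part) == "ct1"
    assert classify_term((0, 2, 1, 3), part) == "ct2"
    assert classify_term((0, 2), part) == "ct1"
    with pytest.raises(IndexError):
        classify_term((0, 9), part)


@pytest.mark.parametrize("seed", range(5))
def test_classify_term_agrees_with_dense_charge_measurement(seed):
    """The label's dN_A equals the charge change measured by applying the
    term as a dense matrix to sharp-charge states."""
    spec = models.ModelSpec(2, 2, 2, 2, lam=1.0, seed=seed)
    ham, part = models.model_hamiltonian(spec)
    basis = oracle.reference_basis(part)
    labels_to_dn = {"intra_A": {0}, "intra_B": {0}, "coulomb_like_AB": {0},
                    "spin_carrying_AB": {0}, "ct1": {1, -1}, "ct2": {2, -2}}
    rng = np.random.default_rng(seed)
    terms = [tuple(rng.integers(0, 4, 4)) for _ in range(12)]
    from fragcas.decompose import ChannelTerm
    for term in terms:
        p, q, r, s = term
        label = classify_term(term, part)
        # dense matrix of 1/2 (pq|rs) sum_st a+_ps a+_rt a_st a_qs
        mono_terms = []
        for sig in (0, 1):
            for tau in (0, 1):
                from fragcas.operators import Monomial
                mono = Monomial(1.0, ((p, sig, 1), (r, tau, 1),
                                      (s, tau, 0), (q, sig, 0)))
                ft = factorize_monomial(mono, part)
                mono_terms.append(ChannelTerm(
                    tuple(("cre" if d else "ann", o, sp)
                          for o, sp, d in ft.op_a),
                    tuple(("cre" if d else "ann", o, sp)
                          for o, sp, d in ft.op_b),
                    ft.coeff * ft.parity_phase))
        m = oracle.dense_operator_matrix(mono_terms, basis)
        if np.abs(m).max() < 1e-14:
            continue
        observed = set()
        for off_k, (sa_k, sb_k) in zip(basis.offsets.values(), basis.blocks):
            blk = m[:, off_k:off_k + sa_k.dim * sb_k.dim]
            for off_b, (sa_b, sb_b) in zip(basis.offsets.values(),
                                           basis.blocks):
                sub = blk[off_b:off_b + sa_b.dim * sb_b.dim]
                if np.abs(sub).max() > 1e-14:
                    observed.add((sa_b.na + sa_b.nb) - (sa_k.na + sa_k.nb))
        assert observed <= labels_to_dn[label], (term, label, observed)


def test_factorize_monomial_recombination():
    """op_A x op_B with the parity phase reproduces the monomial exactly."""
    part = models.ModelSpec(2, 2, 2, 2).partition()
    ham, _ = models.model_hamiltonian(models.ModelSpec(2, 2, lam=1.0,
                                                       seed=13))
    basis = oracle.reference_basis(part)

    def dense_global_monomial(mono):
        """Independent route: apply elementary ops to bitmask determinants."""
        masks = basis.all_bitmasks()
        index = {m: i for i, m in enumerate(masks)}
        na = part.n_orb_a
        nb = part.n_orb_b

        def so_index(orb, spin):
            if orb < na:
                return orb + spin * na
            return 2 * na + (orb - na) + spin * nb

        out = np.zeros((len(masks), len(masks)))
        for j, m0 in enumerate(masks):
            coeff = mono.coeff
            m = m0
            ok = True
            for orb, spin, dag in reversed(mono.ops):
                b = 1 << so_index(orb, spin)
                if dag:
                    if m & b:
                        ok = False
                        break
                    sgn = bin(m & (b - 1)).count("1") % 2
                    m |= b
                else:
                    if not m & b:
                        ok = False
                        break
                    sgn = bin(m & (b - 1)).count("1") % 2
                    m &= ~b
                coeff *= -1.0 if sgn else 1.0
            if ok and m in index:
                out[index[m], j] += coeff
        return out

    from fragcas.decompose import ChannelTerm
    rng = np.random.default_rng(0)
    for mono in rng.choice(expand_monomials(ham), size=25, replace=False):
        ft = factorize_monomial(mono, part)
        term = ChannelTerm(
            tuple(("cre" if d else "ann", o, s) for o, s, d in ft.op_a),
            tuple(("cre" if d else "ann", o, s) for o, s, d in ft.op_b),
            ft.coeff * ft.parity_phase)
        m_fact = oracle.dense_operator_matrix([term], basis)
        m_glob = dense_global_monomial(mono)
        assert np.abs(m_fact - m_glob).max() < 1e-12


def test_mean_field_is_coulomb_minus_half_exchange():
    """For closed-shell RDMs the embedding operator is J - K/2."""
    ham, part = models.model_hamiltonian(models.ModelSpec(3, 3, 2, 2,
                                                          lam=1.0, seed=9))
    n = 3
    rng = np.random.default_rng(1)
    x = rng.normal(size=(n, n))
    w, v = np.linalg.eigh(x @ x.T)
    occ = np.zeros(n)
    occ[:1] = 1.0
    gb_half = (v * occ) @ v.T
    gamma_b = (gb_half, gb_half)
    gamma_a = (np.diag([1.0, 0, 0]), np.diag([1.0, 0, 0]))
    v_a, _, _ = mean_field(ham, part, gamma_a, gamma_b)
    dm = 2 * gb_half     # spin-summed
    g_ab = ham.g[:n, :n, n:, n:]
    j = np.einsum("uvxy,xy->uv", g_ab, dm)
    g_x = ham.g[:n, n:, n:, :n].transpose(0, 3, 2, 1)
    k = np.einsum("uvxy,xy->uv", g_x, dm)
    assert np.abs(v_a[0] - (j - 0.5 * k)).max() < 1e-12
    assert np.abs(v_a[0] - v_a[1]).max() < 1e-14
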