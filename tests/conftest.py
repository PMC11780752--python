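"""Shared fixtures: the expensive N2-dimer desk scan and the seeded-model
property suite are computed once per session and reused across tests."""

import numpy as np
import pytest

from fragcas import models, oracle
from fragcas.decompose import decompose_hamiltonian
from fragcas.embedding import self_consistent_product_state
from fragcas.pt2 import pt2_energies

DESK_BONDS = (1.2, 1.6, 2.0)


@pytest.fixture(scope="session")
def n2_scan():
    """Desk-scale N2-dimer scan with exact CASCI references.

    Three right-bond lengths (equilibrium, intermediate, stretched) at the
    2.0-Angstrom intermolecular separation, CAS(6,6) per fragment.
    """
    from fragcas.pipeline import n2_dimer_point
    records = []
    for bond in DESK_BONDS:
        rec, ps, decomp, extras = n2_dimer_point(bond, with_oracle=True)
        rec.pop("casci_vector", None)
        rec["_ps"] = ps
        rec["_decomp"] = decomp
        records.append(rec)
    return records


def balanced_model_specs(n_models=20):
    """Seeded 2+2 and 3+3 half-filled models for the property suite."""
    specs = []
    for seed in range(n_models):
        if seed % 2 == 0:
            specs.append(models.ModelSpec(n_orb_a=2, n_orb_b=2, n_elec_a=2,
                                          n_elec_b=2, lam=0.15, seed=seed))
        else:
            specs.append(models.ModelSpec(n_orb_a=3, n_orb_b=3, n_elec_a=2,
                                          n_elec_b=2, lam=0.15, seed=seed))
    return specs


@pytest.fixture(scope="session")
def seeded_suite():
    """Embedding + PT2 + oracle quantities on 20 seeded models."""
    out = []
    for spec in balanced_model_specs(20):
        ham, part = models.model_hamiltonian(spec)
        ps = self_consistent_product_state(ham, part)
        decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
        res = pt2_energies(decomp, ps)
        basis = oracle.reference_basis(part)
        h_full = oracle.dense_full_hamiltonian(ham, part, basis)
        h_rec = oracle.dense_decomposition(decomp, basis)
        e2u, e0u, _ = oracle.uncontracted_pt2(decomp, ps.psi_a, ps.psi_b)
        e_exact = oracle.full_casci(ham, spec.n_elec_a + spec.n_elec_b, 0)
        out.append({
            "spec": spec, "ham": ham, "part": part, "ps": ps,
            "decomp": decomp, "res": res,
            "reconstruction_error": float(np.abs(h_full - h_rec).max()),
            "e2_unc": e2u, "e_exact": e_exact,
        })
    return out


@pytest.fixture(scope="session")
def lambda_scan():
    """Uncontracted PT2 residual |E_exact - e0 - e2| along the coupling."""
    lams = np.array([1e-3, 3e-3, 1e-2, 3e-2, 1e-1])
    resid = []
    for lam in lams:
        spec = models.ModelSpec(n_orb_a=2, n_orb_b=2, n_elec_a=2,
                                n_elec_b=2, lam=float(lam), seed=5)
        ham, part = models.model_hamiltonian(spec)
        ps = self_consistent_product_state(ham, part)
        decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
        e2u, _, _ = oracle.uncontracted_pt2(decomp, ps.psi_a, ps.psi_b)
        e_exact = oracle.full_casci(ham, 4, 0)
        resid.append(abs(e_exact - ps.e0 - sum(e2u.values())))
    return lams, np.array(resid)
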