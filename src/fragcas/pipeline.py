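"""High-level drivers: geometry or FCIDUMP input -> embedding + PT2 record.

The result record is a plain dict (JSON-serializable) with the reference,
embedding and per-channel second-order energies, plus diagnostics.
"""

from __future__ import annotations

import numpy as np

from . import oracle
from .decompose import CHANNELS, decompose_hamiltonian
from .embedding import self_consistent_product_state
from .hamiltonian import (ActiveSpaceHamiltonian, FragmentPartition,
                          read_fcidump, read_partition)
from .localize import (build_active_integrals, localize_and_partition,
                       select_active_space)
from .pt2 import pt2_energies
from .scf import Molecule, run_rhf

__all__ = ["run_embedding", "run_from_hamiltonian", "active_space_from_scf",
           "run_from_geometry", "run_from_fcidump"]


def active_space_from_scf(scf, atom_frag, n_active,
                          bias_first_fragment=True):
    """Localize and select fragment active spaces from a converged SCF.

    ``atom_frag``: atom index -> 0 (fragment A) / 1 (fragment B);
    ``n_active``: {"A": (n_occ, n_virt), "B": (n_occ, n_virt)}.
    """
    occ, virt = localize_and_partition(scf, atom_frag, bias_first_fragment)
    c_act, c_core, part = select_active_space(occ, virt, n_active)
    ham = build_active_integrals(scf, c_act, c_core)
    ham.nelec = part.n_elec["A"] + part.n_elec["B"]
    ham.ms2 = part.ms2["A"] + part.ms2["B"]
    return ham, part, (occ, virt)


def run_from_hamiltonian(ham: ActiveSpaceHamiltonian,
                         partition: FragmentPartition,
                         tol_e=1e-9, tol_rdm=1e-7, max_iter=100,
                         damping=0.0, metric_threshold=1e-10,
                         with_oracle=False, e_ref_extra=None,
                         casci_v0=None):
    """Embed, decompose and compute PT2; optionally add exact references."""
    ps = self_consistent_product_state(ham, partition, tol_e=tol_e,
                                       tol_rdm=tol_rdm, max_iter=max_iter,
                                       damping=damping)
    decomp = decompose_hamiltonian(ham, partition, ps.gamma_a, ps.gamma_b)
    res = pt2_energies(decomp, ps, metric_threshold)
    record = {
        "e_product_reference": ps.e_ref,
        "e0": ps.e0,
        "e2": {name: res.channels[name].e2 for name in CHANNELS},
        "e2_total": res.e2_total,
        "e_total": res.e_total,
        "first_order": res.first_order,
        "n_iterations": len(ps.iteration_log),
        "diagnostics": {
            name: {"members": res.channels[name].n_members,
                   "kept": res.channels[name].n_kept,
                   "min_metric_eig": res.channels[name].min_metric_eig,
                   "posdef_warning": res.channels[name].posdef_warning,
                   "residual": res.channels[name].residual}
            for name in CHANNELS},
    }
    if e_ref_extra:
        record.update(e_ref_extra)
    if with_oracle:
        n_elec = partition.n_elec["A"] + partition.n_elec["B"]
        ms2 = partition.ms2["A"] + partition.ms2["B"]
        record["e_exact"] = oracle.full_casci(ham, n_elec, ms2, v0=casci_v0)
        basis_dim = oracle.reference_basis(partition).dim
        if basis_dim <= oracle.DENSE_CAP:
            e2u, e0u, dim1 = oracle.uncontracted_pt2(decomp, ps.psi_a,
                                                     ps.psi_b)
            record["e2_uncontracted"] = e2u
            record["e2_uncontracted_total"] = sum(e2u.values())
    return record, ps, decomp


def run_from_geometry(symbols, coords_angstrom, atom_frag, n_active,
                      basis="sto-3g", charge=0, with_oracle=False,
                      bias_first_fragment=True, **kwargs):
    """Full pipeline from a molecular geometry (Angstrom)."""
    mol = Molecule.from_angstrom(symbols, coords_angstrom, charge)
    scf = run_rhf(mol, basis)
    ham, part, _ = active_space_from_scf(scf, atom_frag, n_active,
                                         bias_first_fragment)
    record, ps, decomp = run_from_hamiltonian(
        ham, part, with_oracle=with_oracle,
        e_ref_extra={"e_hf": scf.e_tot}, **kwargs)
    record["basis"] = basis
    return record, ps, decomp, (ham, part, scf)


def run_from_fcidump(fcidump_path, partition_path, with_oracle=False,
                     **kwargs):
    """Full pipeline from an FCIDUMP + partition file pair."""
    ham = read_fcidump(fcidump_path)
    part = read_partition(partition_path)
    return run_from_hamiltonian(ham, part, with_oracle=with_oracle, **kwargs)


def run_embedding(*args, **kwargs):
    """Alias of :func:`run_from_hamiltonian` (embedding-centric name)."""
    return run_from_hamiltonian(*args, **kwargs)


def n2_dimer_point(bond_right, separation=2.0, bond_left=1.2,
                   basis="sto-3g", with_oracle=False, casci_v0=None,
                   **kwargs):
    """One point of the N2-dimer scan: CAS(6,6) per fragment (triple bond)."""
    from .models import n2_dimer_geometry
    symbols, coords = n2_dimer_geometry(separation, bond_left, bond_right)
    atom_frag = [0, 0, 1, 1]
    n_active = {"A": (3, 3), "B": (3, 3)}
    record, ps, decomp, extras = run_from_geometry(
        symbols, coords, atom_frag, n_active, basis=basis,
        with_oracle=False, **kwargs)
    ham, part, scf = extras
    if with_oracle:
        if casci_v0 is None:
            casci_v0 = oracle.product_guess_vector(ps.psi_a, ps.psi_b, part)
        record["e_exact"], vec = oracle.full_casci(
            ham, 12, 0, return_vector=True, v0=casci_v0, tol=1e-6)
        record["casci_vector"] = vec
    record["bond_right"] = bond_right
    return record, ps, decomp, extras
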