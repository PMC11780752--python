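"""Minimal restricted Hartree-Fock backend over the bundled Gaussian bases.

Provides the canonical molecular orbitals, Fock matrix and AO integrals the
localization and active-space machinery consumes.  Closed-shell RHF with a
core-Hamiltonian guess and DIIS convergence acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .basis import ELEMENT_Z, build_basis
from .integrals import ao_integrals
from .models import ANGSTROM_TO_BOHR

__all__ = ["Molecule", "SCFResult", "run_rhf"]


@dataclass
class Molecule:
    symbols: list
    coords: np.ndarray          # (n, 3) in bohr
    charge: int = 0

    @classmethod
    def from_angstrom(cls, symbols, coords_angstrom, charge=0):
        return cls(list(symbols),
                   np.asarray(coords_angstrom, float) * ANGSTROM_TO_BOHR,
                   charge)

    @classmethod
    def from_xyz(cls, path, charge=0):
        with open(path) as fh:
            lines = fh.read().strip().splitlines()
        n = int(lines[0].split()[0])
        symbols, coords = [], []
        for line in lines[2:2 + n]:
            parts = line.split()
            symbols.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        return cls.from_angstrom(symbols, np.array(coords), charge)

    @property
    def charges(self):
        return np.array([ELEMENT_Z[s] for s in self.symbols], float)

    @property
    def n_electrons(self) -> int:
        return int(self.charges.sum()) - self.charge

    def nuclear_repulsion(self) -> float:
        e = 0.0
        z = self.charges
        for i in range(len(z)):
            for j in range(i):
                e += z[i] * z[j] / np.linalg.norm(self.coords[i]
                                                  - self.coords[j])
        return e


@dataclass
class SCFResult:
    mol: Molecule
    shells: list
    S: np.ndarray
    hcore: np.ndarray
    eri: np.ndarray
    C: np.ndarray               # AO x MO coefficients
    eps: np.ndarray             # orbital energies
    F: np.ndarray               # converged AO Fock matrix
    e_tot: float
    e_nuc: float
    n_occ: int
    ao_atom: np.ndarray         # AO index -> atom index

    @property
    def n_ao(self) -> int:
        return self.S.shape[0]


def _fock(hcore, eri, dm):
    j = np.einsum("pqrs,rs->pq", eri, dm, optimize=True)
    k = np.einsum("prqs,rs->pq", eri, dm, optimize=True)
    return hcore + j - 0.5 * k


def _scf_loop(hcore, g, S, x, n_occ, dm0, conv, max_iter, damp_steps=8):
    """Damped iterations followed by DIIS; returns (e_el, dm, F)."""
    dm = dm0
    diis_f, diis_e = [], []
    e_old = None
    f = _fock(hcore, g, dm)
    for it in range(max_iter):
        eps, c_p = np.linalg.eigh(x.T @ f @ x)
        C = x @ c_p
        dm_new = 2.0 * C[:, :n_occ] @ C[:, :n_occ].T
        if it < damp_steps:
            dm_new = 0.5 * dm_new + 0.5 * dm
        f = _fock(hcore, g, dm_new)
        e_el = 0.5 * np.einsum("pq,pq->", dm_new, hcore + f)
        if e_old is not None and np.abs(dm_new - dm).max() < conv * 100 \
                and abs(e_el - e_old) < conv:
            return e_el, dm_new, f
        dm = dm_new
        e_old = e_el
        if it < damp_steps:
            continue
        err = f @ dm @ S - S @ dm @ f
        diis_f.append(f.copy())
        diis_e.append(err.copy())
        if len(diis_f) > 8:
            diis_f.pop(0)
            diis_e.pop(0)
        if len(diis_f) >= 2:
            m = len(diis_f)
            B = np.empty((m + 1, m + 1))
            B[-1, :] = -1.0
            B[:, -1] = -1.0
            B[-1, -1] = 0.0
            for i in range(m):
                for j in range(m):
                    B[i, j] = np.einsum("pq,pq->", diis_e[i], diis_e[j])
            rhs = np.zeros(m + 1)
            rhs[-1] = -1.0
            try:
                w = np.linalg.solve(B, rhs)[:m]
                f = sum(wi * fi for wi, fi in zip(w, diis_f))
            except np.linalg.LinAlgError:
                pass
    raise RuntimeError("RHF did not converge")


def run_rhf(mol: Molecule, basis: str = "sto-3g", conv: float = 1e-10,
            max_iter: int = 300, n_restarts: int = 3) -> SCFResult:
    """Closed-shell RHF; raises for odd electron counts.

    To avoid converging onto aufbau-violating stationary points (which the
    core-Hamiltonian guess can produce for multiply bonded systems), a few
    deterministic jittered restarts are run and the lowest solution kept.
    """
    if mol.n_electrons % 2:
        raise ValueError("restricted HF needs an even electron count")
    shells = build_basis(mol.symbols, mol.coords, basis)
    S, hcore, g = ao_integrals(shells, mol.charges, mol.coords)
    n_occ = mol.n_electrons // 2
    e_nuc = mol.nuclear_repulsion()
    nbf = S.shape[0]

    x = sla.fractional_matrix_power(S, -0.5).real
    eps0, c_p = np.linalg.eigh(x.T @ hcore @ x)
    c0 = x @ c_p
    dm0 = 2.0 * c0[:, :n_occ] @ c0[:, :n_occ].T
    e_el, dm, f = _scf_loop(hcore, g, S, x, n_occ, dm0, conv, max_iter)
    rng = np.random.default_rng(2024)
    for _ in range(n_restarts):
        q, _ = np.linalg.qr(np.eye(nbf) + 0.3 * rng.normal(size=(nbf, nbf)))
        ct = c0 @ q
        dmt = 2.0 * ct[:, :n_occ] @ ct[:, :n_occ].T
        try:
            e_t, dm_t, f_t = _scf_loop(hcore, g, S, x, n_occ, dmt, conv,
                                       max_iter)
        except RuntimeError:
            continue
        if e_t < e_el - 1e-9:
            e_el, dm, f = e_t, dm_t, f_t
    eps, c_p = np.linalg.eigh(x.T @ f @ x)
    C = x @ c_p
    # deterministic orbital phases
    for k in range(C.shape[1]):
        i = int(np.argmax(np.abs(C[:, k])))
        if C[i, k] < 0:
            C[:, k] = -C[:, k]
    e_el = 0.5 * np.einsum("pq,pq->", dm, hcore + f)
    ao_atom = np.concatenate([[sh.atom_index] * sh.n_comp for sh in shells])
    return SCFResult(mol, shells, S, hcore, g, C, eps, f,
                     float(e_el + e_nuc), e_nuc, n_occ,
                     ao_atom.astype(int))
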