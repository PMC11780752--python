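"""Fragment-localized molecular orbitals and active-space selection.

Pipeline: Pipek-Mezey localization (gross Mulliken population per fragment
as the localization functional) of the occupied and valence-virtual blocks
separately; fragment assignment by largest population with a bias that sends
ambiguous bond/antibond orbitals (population below a threshold on either
side, as happens for a covalent bond cut by the fragmentation) to the first
fragment; recanonicalization by block-diagonalizing the Fock matrix within
each (fragment x occupation) block, giving quasi-energies; active-space
selection per fragment by quasi-energy ordering; frozen-core contraction of
the integrals into an ActiveSpaceHamiltonian plus FragmentPartition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonian import ActiveSpaceHamiltonian, FragmentPartition
from .scf import SCFResult, _fock

__all__ = ["LocalizedOrbitalSet", "pipek_mezey_localize", "assign_fragments",
           "recanonicalize", "select_active_space", "build_active_integrals",
           "localize_and_partition", "fragment_populations"]


def fragment_populations(C, S, ao_frag, n_frag=2) -> np.ndarray:
    """Gross Mulliken population of each orbital on each fragment: (n_mo, F)."""
    sc = S @ C
    pop = C * sc            # (ao, mo) per-AO gross populations
    out = np.zeros((C.shape[1], n_frag))
    for f in range(n_frag):
        out[:, f] = pop[ao_frag == f].sum(axis=0)
    return out


def pipek_mezey_localize(C_block, S, ao_frag, tol=1e-10, max_sweeps=200):
    """Jacobi-sweep maximization of sum_i sum_F Q_iF^2 over one MO block.

    Input orbitals must be orthonormal under S; the metric is non-decreasing
    every sweep and the rotation is stopped when a full sweep gains less
    than ``tol``.
    """
    C = np.array(C_block, float)
    n_mo = C.shape[1]
    if n_mo == 0:
        return C
    ortho = C.T @ S @ C - np.eye(n_mo)
    if np.abs(ortho).max() > 1e-8:
        raise ValueError("input orbitals not orthonormal under S")
    frags = sorted(set(int(f) for f in ao_frag))
    sc = None

    def metric(C):
        pop = fragment_populations(C, S, ao_frag, n_frag=len(frags))
        return float((pop ** 2).sum())

    cur = metric(C)
    for sweep in range(max_sweeps):
        gain_total = 0.0
        sc = S @ C
        for i in range(n_mo):
            for j in range(i + 1, n_mo):
                a_sum = 0.0
                b_sum = 0.0
                for f in frags:
                    m = ao_frag == f
                    qii = C[m, i] @ sc[m, i]
                    qjj = C[m, j] @ sc[m, j]
                    qij = 0.5 * (C[m, i] @ sc[m, j] + C[m, j] @ sc[m, i])
                    a_sum += qij ** 2 - 0.25 * (qii - qjj) ** 2
                    b_sum += qij * (qii - qjj)
                r = np.hypot(a_sum, b_sum)
                if r < 1e-16:
                    continue
                gain = a_sum + r
                if gain < 1e-15:
                    continue
                # rotation angle from cos(4t) = -A/r, sin(4t) = B/r
                t4 = np.arctan2(b_sum, -a_sum)
                theta = 0.25 * t4
                c, s = np.cos(theta), np.sin(theta)
                ci = C[:, i].copy()
                C[:, i] = c * ci + s * C[:, j]
                C[:, j] = -s * ci + c * C[:, j]
                sci = sc[:, i].copy()
                sc[:, i] = c * sci + s * sc[:, j]
                sc[:, j] = -s * sci + c * sc[:, j]
                gain_total += gain
        new = metric(C)
        if new < cur - 1e-9:
            raise RuntimeError("PM metric decreased (numerical problem)")
        if new - cur < tol:
            break
        cur = new
    return C


def assign_fragments(C_loc, S, ao_frag, bias_first_fragment=True,
                     threshold=0.7):
    """Fragment label (0/1) per localized orbital.

    Orbitals whose largest fragment population is below ``threshold``
    (bond/antibond pairs across the fragment cut) go to fragment 0 when the
    bias flag is set.
    """
    pop = fragment_populations(C_loc, S, ao_frag)
    label = np.argmax(pop, axis=1)
    if bias_first_fragment:
        label[pop.max(axis=1) < threshold] = 0
    return label, pop


def recanonicalize(F_ao, C_loc, labels):
    """Rotate within each fragment block so the projected Fock is diagonal.

    Returns (C_rot, quasi_energies); orbitals stay within their block.
    """
    C = np.array(C_loc, float)
    qe = np.zeros(C.shape[1])
    for lab in sorted(set(labels.tolist())):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) == 0:
            continue
        f_blk = C[:, idx].T @ F_ao @ C[:, idx]
        w, u = np.linalg.eigh(0.5 * (f_blk + f_blk.T))
        C[:, idx] = C[:, idx] @ u
        qe[idx] = w
    return C, qe


@dataclass
class LocalizedOrbitalSet:
    """Localized, fragment-assigned, recanonicalized orbitals of one block."""

    C: np.ndarray               # AO x MO
    fragment: np.ndarray        # 0 (A) / 1 (B) per orbital
    quasi_energy: np.ndarray
    occ_class: str              # "occupied" or "virtual"
    population: np.ndarray      # max fragment population per orbital


def _localize_block(scf: SCFResult, mo_idx, atom_frag, occ_class,
                    bias_first):
    ao_frag = np.array([atom_frag[a] for a in scf.ao_atom])
    C_blk = scf.C[:, mo_idx]
    C_loc = pipek_mezey_localize(C_blk, scf.S, ao_frag)
    labels, pop = assign_fragments(C_loc, scf.S, ao_frag, bias_first)
    C_rot, qe = recanonicalize(scf.F, C_loc, labels)
    order = np.lexsort((qe, labels))
    return LocalizedOrbitalSet(C_rot[:, order], labels[order], qe[order],
                               occ_class, pop.max(axis=1)[order])


def localize_and_partition(scf: SCFResult, atom_frag,
                           bias_first_fragment=True):
    """Localized occupied and valence-virtual sets for a two-fragment split.

    ``atom_frag`` maps atom index -> 0/1.  All virtuals of the bundled
    minimal/split-valence bases are valence virtuals (no hard virtuals are
    produced), so the whole virtual block is localized.
    """
    n_occ = scf.n_occ
    occ = _localize_block(scf, np.arange(n_occ), atom_frag, "occupied",
                          bias_first_fragment)
    virt = _localize_block(scf, np.arange(n_occ, scf.n_ao), atom_frag,
                           "virtual", bias_first_fragment)
    return occ, virt


class SelectionError(ValueError):
    pass


def select_active_space(occ: LocalizedOrbitalSet, virt: LocalizedOrbitalSet,
                        n_active: dict):
    """Pick per-fragment active orbitals by quasi-energy ordering.

    ``n_active`` is {"A": (n_occ, n_virt), "B": (n_occ, n_virt)}.  The
    highest-quasi-energy occupied and lowest-quasi-energy virtual localized
    orbitals of each fragment become active; each fragment gets
    ``2 * n_occ`` electrons.  Returns (C_active, C_core, partition).
    """
    act_cols_a, act_cols_b, core_cols = [], [], []
    for lab, frag_char in ((0, "A"), (1, "B")):
        n_o, n_v = n_active[frag_char]
        oc_idx = np.nonzero(occ.fragment == lab)[0]
        vt_idx = np.nonzero(virt.fragment == lab)[0]
        if n_o > len(oc_idx) or n_v > len(vt_idx):
            raise SelectionError(
                f"fragment {frag_char}: requested ({n_o},{n_v}) active "
                f"orbitals, available ({len(oc_idx)},{len(vt_idx)})")
        oc_sorted = oc_idx[np.argsort(occ.quasi_energy[oc_idx])]
        vt_sorted = vt_idx[np.argsort(virt.quasi_energy[vt_idx])]
        chosen_occ = list(oc_sorted[len(oc_sorted) - n_o:])
        chosen_virt = list(vt_sorted[:n_v])
        cols = [occ.C[:, i] for i in chosen_occ] + \
            [virt.C[:, i] for i in chosen_virt]
        if lab == 0:
            act_cols_a = cols
        else:
            act_cols_b = cols
        core_cols.extend(occ.C[:, i] for i in oc_sorted[:len(oc_sorted) - n_o])
    c_active = np.array(act_cols_a + act_cols_b).T
    c_core = (np.array(core_cols).T if core_cols
              else np.zeros((occ.C.shape[0], 0)))
    part = FragmentPartition(
        len(act_cols_a), len(act_cols_b),
        {"A": 2 * n_active["A"][0], "B": 2 * n_active["B"][0]},
        {"A": 0, "B": 0})
    return c_active, c_core, part


def build_active_integrals(scf: SCFResult, c_active, c_core) \
        -> ActiveSpaceHamiltonian:
    """Frozen-core contraction into an active-space Hamiltonian."""
    dm_core = 2.0 * c_core @ c_core.T
    f_core = _fock(scf.hcore, scf.eri, dm_core)
    h_act = c_active.T @ f_core @ c_active
    e_core = scf.e_nuc + 0.5 * np.einsum("pq,pq->", dm_core,
                                         scf.hcore + f_core)
    g_act = np.einsum("pqrs,pi,qj,rk,sl->ijkl", scf.eri, c_active, c_active,
                      c_active, c_active, optimize=True)
    n_act = c_active.shape[1]
    return ActiveSpaceHamiltonian(n_act, float(e_core),
                                  0.5 * (h_act + h_act.T), g_act)
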