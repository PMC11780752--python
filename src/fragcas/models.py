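"""Deterministic test-model generators: seeded two-fragment Hamiltonians
with tunable interfragment coupling, and the benchmark molecular geometries.

The random ensemble emulates a small correlated active space: spread
one-electron levels with weak off-diagonal mixing, repulsive on-diagonal
Coulomb integrals with moderate random two-electron structure, and *every*
integral whose indices cross the fragment boundary scaled by a coupling
``lam`` in [0, 1].  At ``lam = 0`` the fragments are exactly independent;
small ``lam`` is the regime where second-order perturbation theory on the
interfragment interaction is controlled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hamiltonian import (ActiveSpaceHamiltonian, FragmentPartition,
                          symmetrize_g)

__all__ = ["ModelSpec", "model_hamiltonian", "n2_dimer_geometry",
           "butadiene_geometry"]

ANGSTROM_TO_BOHR = 1.0 / 0.529177210903


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a seeded synthetic two-fragment Hamiltonian."""

    n_orb_a: int = 2
    n_orb_b: int = 2
    n_elec_a: int = 2
    n_elec_b: int = 2
    ms2_a: int = 0
    ms2_b: int = 0
    lam: float = 0.1
    seed: int = 0
    style: str = "random_symmetric"   # or "hubbard_chain"
    hubbard_u: float = 4.0
    hubbard_t: float = 1.0

    def partition(self) -> FragmentPartition:
        return FragmentPartition(self.n_orb_a, self.n_orb_b,
                                 {"A": self.n_elec_a, "B": self.n_elec_b},
                                 {"A": self.ms2_a, "B": self.ms2_b})


def _cross_mask(n, na):
    in_a = np.arange(n) < na
    m2 = in_a[:, None] != in_a[None, :]
    f = in_a.astype(int)
    cnt = (f[:, None, None, None] + f[None, :, None, None]
           + f[None, None, :, None] + f[None, None, None, :])
    m4 = (cnt != 0) & (cnt != 4)
    return m2, m4


def model_hamiltonian(spec: ModelSpec):
    """Build (ActiveSpaceHamiltonian, FragmentPartition) from a ModelSpec.

    Identical specs give bit-identical tensors.
    """
    part = spec.partition()
    n = spec.n_orb_a + spec.n_orb_b
    if spec.style == "hubbard_chain":
        h = np.zeros((n, n))
        for p in range(n - 1):
            t = spec.hubbard_t
            if p == spec.n_orb_a - 1:          # the interfragment bond
                t = t * spec.lam
            h[p, p + 1] = h[p + 1, p] = -t
        g = np.zeros((n, n, n, n))
        for p in range(n):
            g[p, p, p, p] = spec.hubbard_u
        return (ActiveSpaceHamiltonian(n, 0.0, h, g,
                                       nelec=spec.n_elec_a + spec.n_elec_b,
                                       ms2=spec.ms2_a + spec.ms2_b), part)
    if spec.style != "random_symmetric":
        raise ValueError(f"unknown model style {spec.style!r}")

    rng = np.random.default_rng(spec.seed)
    # spread orbital levels so fragment ground states are non-degenerate
    levels = np.concatenate([
        -2.0 + 0.7 * np.arange(spec.n_orb_a),
        -1.8 + 0.7 * np.arange(spec.n_orb_b)])
    h = np.diag(levels + 0.05 * rng.normal(size=n))
    off = 0.1 * rng.normal(size=(n, n))
    h = h + np.triu(off, 1) + np.triu(off, 1).T

    g = 0.05 * rng.normal(size=(n, n, n, n))
    g = symmetrize_g(g)
    for p in range(n):
        g[p, p, p, p] += 0.8
        for q in range(n):
            if q != p:
                g[p, p, q, q] += 0.3 / (1.0 + abs(p - q))
                g[q, q, p, p] = g[p, p, q, q]

    m2, m4 = _cross_mask(n, spec.n_orb_a)
    h = np.where(m2, spec.lam * h, h)
    g = np.where(m4, spec.lam * g, g)
    e_core = float(rng.normal() * 0.1)
    return (ActiveSpaceHamiltonian(n, e_core, h, g,
                                   nelec=spec.n_elec_a + spec.n_elec_b,
                                   ms2=spec.ms2_a + spec.ms2_b), part)


# ---------------------------------------------------------------------------
# Benchmark geometries (coordinates in Angstrom; symbols, (n,3) array)


def n2_dimer_geometry(separation: float = 2.0, bond_left: float = 1.2,
                      bond_right: float = 1.2):
    """Two parallel N2 molecules, centers ``separation`` apart.

    Each molecule lies along z; the centers are displaced along x.  The
    right molecule's bond length is the scan coordinate for stretching one
    fragment toward dissociation.
    """
    if min(separation, bond_left, bond_right) <= 0:
        raise ValueError("lengths must be positive")
    coords = np.array([
        [0.0, 0.0, +bond_left / 2],
        [0.0, 0.0, -bond_left / 2],
        [separation, 0.0, +bond_right / 2],
        [separation, 0.0, -bond_right / 2],
    ])
    return ["N", "N", "N", "N"], coords


def butadiene_geometry(stretch: float = 0.0):
    """Planar s-trans butadiene from idealized bond parameters.

    ``stretch`` elongates the terminal double bond C1=C2 (fragment A's
    double bond) by displacing the terminal CH2 group along the bond axis.
    Atom order: C1 C2 C3 C4 then the six hydrogens; the natural fragment
    split is atoms of (C1,C2) vs (C3,C4) with the middle C2-C3 single bond
    cut.
    """
    r_cc_double = 1.34
    r_cc_single = 1.47
    r_ch = 1.09
    c = np.cos(np.pi / 3.0)   # 120 degree internal angles
    s = np.sin(np.pi / 3.0)

    c2 = np.array([0.0, 0.0, 0.0])
    c3 = np.array([r_cc_single, 0.0, 0.0])
    d21 = np.array([-c, s, 0.0])            # C2 -> C1 direction
    d34 = np.array([c, -s, 0.0])            # C3 -> C4 direction
    c1 = c2 + r_cc_double * d21
    c4 = c3 + r_cc_double * d34

    def h_at(center, direction):
        return center + r_ch * direction / np.linalg.norm(direction)

    # trigonal hydrogens from exact 120-degree in-plane rotations
    def unit(v):
        return v / np.linalg.norm(v)

    def rot120(v, sign=1):
        th = sign * 2 * np.pi / 3
        rotz = np.array([[np.cos(th), -np.sin(th), 0],
                         [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        return rotz @ v

    h1a = h_at(c1, rot120(unit(c2 - c1)))
    h1b = h_at(c1, rot120(unit(c2 - c1), -1))
    h2 = h_at(c2, rot120(unit(c1 - c2)))
    h3 = h_at(c3, rot120(unit(c4 - c3)))
    h4a = h_at(c4, rot120(unit(c3 - c4)))
    h4b = h_at(c4, rot120(unit(c3 - c4), -1))

    if stretch:
        shift = stretch * unit(c1 - c2)
        for v in (c1, h1a, h1b):
            v += shift

    symbols = ["C", "C", "C", "C", "H", "H", "H", "H", "H", "H"]
    coords = np.array([c1, c2, c3, c4, h1a, h1b, h2, h3, h4a, h4b])
    return symbols, coords


def xyz_string(symbols, coords, comment="") -> str:
    lines = [str(len(symbols)), comment]
    for sym, (x, y, z) in zip(symbols, coords):
        lines.append(f"{sym} {x:18.12f} {y:18.12f} {z:18.12f}")
    return "\n".join(lines) + "\n"
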