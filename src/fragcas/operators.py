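"""Second-quantized operator bookkeeping across a two-fragment split.

The Hamiltonian is expanded into spin-orbital monomials in globally
normal-ordered form::

    H = e_core + sum_pq,s h[p,q] a+_ps a_qs
        + 1/2 sum_pqrs,st g[p,q,r,s] a+_ps a+_rt a_st a_qs

Each monomial factorizes uniquely into (A-operators)(B-operators) times a
parity phase, because operators on disjoint fragments anticommute freely and
the sub-sequences of a (creations...annihilations) string are themselves
normal-ordered.  The global spin-orbital ordering is fragment A (alpha block,
then beta block) followed by fragment B; all phases are relative to it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hamiltonian import ActiveSpaceHamiltonian, FragmentPartition

__all__ = ["classify_term", "Monomial", "expand_monomials",
           "FragmentOperatorTerm", "factorize_monomial"]


def _in_a(p: int, part: FragmentPartition) -> bool:
    return p < part.n_orb_a


def classify_term(term: tuple, partition: FragmentPartition) -> str:
    """Classify a one-/two-electron integral term by its fragment pattern.

    ``term`` is ``(p, q)`` for ``h[p,q] E_pq`` or ``(p, q, r, s)`` for the
    ``(pq|rs)`` interaction.  The label encodes the net particle-number
    change on fragment A and, for number-conserving interfragment terms,
    whether the term is a density-density (coulomb_like) or an operator
    exchange (spin_carrying) interaction.
    """
    for p in term:
        if not 0 <= p < partition.n_orb:
            raise IndexError(f"orbital index {p} out of range")
    flags = [_in_a(p, partition) for p in term]
    if len(term) == 2:
        pa, qa = flags
        if pa and qa:
            return "intra_A"
        if not pa and not qa:
            return "intra_B"
        return "ct1"
    pa, qa, ra, sa = flags
    dn = int(pa) - int(qa) + int(ra) - int(sa)
    if abs(dn) == 2:
        return "ct2"
    if abs(dn) == 1:
        return "ct1"
    if all(flags):
        return "intra_A"
    if not any(flags):
        return "intra_B"
    if pa == qa and ra == sa:
        return "coulomb_like_AB"
    return "spin_carrying_AB"


@dataclass(frozen=True)
class Monomial:
    """coeff times a product of elementary operators in fixed order.

    ``ops`` is a tuple of ``(orb, spin, dag)`` with global orbital indices,
    spin 0/1 and dag 1 for creation.  The product is read left to right.
    """

    coeff: float
    ops: tuple


def expand_monomials(ham: ActiveSpaceHamiltonian, cut: float = 1e-14):
    """Spin-orbital monomials of H (excluding the scalar e_core)."""
    n = ham.n_orb
    out = []
    for p in range(n):
        for q in range(n):
            c = ham.h[p, q]
            if abs(c) <= cut:
                continue
            for s in (0, 1):
                out.append(Monomial(c, ((p, s, 1), (q, s, 0))))
    for p in range(n):
        for q in range(n):
            for r in range(n):
                for s in range(n):
                    c = 0.5 * ham.g[p, q, r, s]
                    if abs(c) <= cut:
                        continue
                    for sig in (0, 1):
                        for tau in (0, 1):
                            out.append(Monomial(
                                c, ((p, sig, 1), (r, tau, 1),
                                    (s, tau, 0), (q, sig, 0))))
    return out


@dataclass(frozen=True)
class FragmentOperatorTerm:
    """A Hamiltonian monomial in fragment-factorized form.

    ``op_a``/``op_b`` are tuples of ``(local_orb, spin, dag)`` acting only on
    their fragment, in the same relative order as in the parent monomial.
    ``parity_phase`` is the sign of moving all B operators to the right of
    all A operators; ``coeff * parity_phase * op_a * op_b`` reproduces the
    original monomial.
    """

    coeff: float
    op_a: tuple
    op_b: tuple
    parity_phase: int

    @property
    def dn_a(self) -> int:
        return sum(1 if dag else -1 for _, _, dag in self.op_a)


def factorize_monomial(mono: Monomial,
                       partition: FragmentPartition) -> FragmentOperatorTerm:
    """Split a monomial into A and B sub-sequences with the interleave sign."""
    n_a = partition.n_orb_a
    op_a, op_b = [], []
    sign = 1
    for orb, spin, dag in mono.ops:
        if orb < n_a:
            # an A operator jumps over every B operator already collected
            if len(op_b) % 2 == 1:
                sign = -sign
            op_a.append((orb, spin, dag))
        else:
            op_b.append((orb - n_a, spin, dag))
    return FragmentOperatorTerm(mono.coeff, tuple(op_a), tuple(op_b), sign)
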