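"""Active-space Hamiltonians and fragment partitions.

The central container is :class:`ActiveSpaceHamiltonian`: a core energy, a
one-electron integral matrix ``h`` and a two-electron integral tensor ``g`` in
the chemists' convention ``g[p,q,r,s] = (pq|rs)``, all in Hartree over a set
of orthonormal active spatial orbitals.  The second-quantized operator it
represents is::

    H = e_core + sum_pq h[p,q] E_pq
             + 1/2 sum_pqrs g[p,q,r,s] (E_pq E_rs - delta_qr E_ps)

with spin-summed excitation operators ``E_pq = sum_s a+_ps a_qs``.

A :class:`FragmentPartition` splits the active orbitals into two fragments A
and B (A orbitals first, by convention) and fixes each fragment's electron
number and spin projection Sz.  Plain-text I/O is provided for the standard
FCIDUMP integral format and for a small partition-file format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ActiveSpaceHamiltonian",
    "FragmentPartition",
    "read_fcidump",
    "write_fcidump",
    "read_partition",
    "write_partition",
]

SYM_TOL = 1e-10


@dataclass
class ActiveSpaceHamiltonian:
    """Second-quantized Hamiltonian over ``n_orb`` active spatial orbitals.

    Parameters
    ----------
    n_orb:
        Number of active spatial orbitals (>= 2 for fragment work, 1 allowed
        for degenerate toy cases).
    e_core:
        Scalar core energy (nuclear repulsion plus any frozen-core mean
        field), Hartree.
    h:
        ``(n_orb, n_orb)`` symmetric one-electron integrals, Hartree.
    g:
        ``(n_orb,)*4`` two-electron integrals ``(pq|rs)`` with 8-fold
        permutational symmetry, Hartree.
    """

    n_orb: int
    e_core: float
    h: np.ndarray
    g: np.ndarray
    # optional FCIDUMP metadata (total electrons / 2*Sz), not used by algebra
    nelec: int | None = None
    ms2: int | None = None

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        self.validate()

    def validate(self):
        n = self.n_orb
        if n < 1:
            raise ValueError("n_orb must be >= 1")
        if self.h.shape != (n, n):
            raise ValueError(f"h has shape {self.h.shape}, expected {(n, n)}")
        if self.g.shape != (n, n, n, n):
            raise ValueError(f"g has shape {self.g.shape}")
        if not (np.isfinite(self.e_core) and np.isfinite(self.h).all()
                and np.isfinite(self.g).all()):
            raise ValueError("non-finite integrals")
        if np.abs(self.h - self.h.T).max() > SYM_TOL:
            raise ValueError("h is not symmetric")
        g = self.g
        for perm in [(1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1)]:
            if np.abs(g - g.transpose(perm)).max() > SYM_TOL:
                raise ValueError(f"g violates permutational symmetry {perm}")

    def copy(self) -> "ActiveSpaceHamiltonian":
        return ActiveSpaceHamiltonian(self.n_orb, self.e_core,
                                      self.h.copy(), self.g.copy(),
                                      self.nelec, self.ms2)

    def rotated(self, u: np.ndarray) -> "ActiveSpaceHamiltonian":
        """Transform integrals by an orthogonal orbital rotation ``u``."""
        h = u.T @ self.h @ u
        g = np.einsum("pqrs,pi,qj,rk,sl->ijkl", self.g, u, u, u, u,
                      optimize=True)
        return ActiveSpaceHamiltonian(self.n_orb, self.e_core, h, g,
                                      self.nelec, self.ms2)


def symmetrize_g(g: np.ndarray) -> np.ndarray:
    """Average a rank-4 tensor over the 8 chemists'-convention permutations."""
    return (g + g.transpose(1, 0, 2, 3) + g.transpose(0, 1, 3, 2)
            + g.transpose(1, 0, 3, 2) + g.transpose(2, 3, 0, 1)
            + g.transpose(3, 2, 0, 1) + g.transpose(2, 3, 1, 0)
            + g.transpose(3, 2, 1, 0)) / 8.0


@dataclass
class FragmentPartition:
    """Orbital -> fragment map plus per-fragment (n_elec, 2*Sz) sectors.

    Orbitals are 0-based; all A orbitals must precede all B orbitals, so the
    partition is fully specified by ``n_orb_A``/``n_orb_B``.  ``ms2`` is the
    integer 2*Sz of each fragment.
    """

    n_orb_a: int
    n_orb_b: int
    n_elec: dict = field(default_factory=dict)   # {"A": int, "B": int}
    ms2: dict = field(default_factory=dict)      # {"A": int, "B": int}

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_orb_a < 1 or self.n_orb_b < 1:
            raise ValueError("both fragments must contain orbitals")
        for lab, n_orb in (("A", self.n_orb_a), ("B", self.n_orb_b)):
            ne = self.n_elec[lab]
            m = self.ms2[lab]
            if not (0 <= ne <= 2 * n_orb):
                raise ValueError(f"fragment {lab}: n_elec={ne} out of range")
            if abs(m) > ne or (ne - m) % 2:
                raise ValueError(f"fragment {lab}: ms2={m} incompatible "
                                 f"with n_elec={ne}")
            if (ne + abs(m)) // 2 > n_orb:
                raise ValueError(f"fragment {lab}: spin sector needs more "
                                 f"than {n_orb} orbitals")

    @property
    def n_orb(self) -> int:
        return self.n_orb_a + self.n_orb_b

    def fragment_of(self, p: int) -> str:
        if not 0 <= p < self.n_orb:
            raise IndexError(p)
        return "A" if p < self.n_orb_a else "B"

    def orbitals(self, label: str) -> np.ndarray:
        if label == "A":
            return np.arange(self.n_orb_a)
        return np.arange(self.n_orb_a, self.n_orb)

    def n_orb_frag(self, label: str) -> int:
        return self.n_orb_a if label == "A" else self.n_orb_b

    def n_alpha(self, label: str) -> int:
        return (self.n_elec[label] + self.ms2[label]) // 2

    def n_beta(self, label: str) -> int:
        return (self.n_elec[label] - self.ms2[label]) // 2

    def sector(self, label: str) -> tuple:
        """(n_orb, n_alpha, n_beta) of one fragment's CI sector."""
        return (self.n_orb_frag(label), self.n_alpha(label),
                self.n_beta(label))

    def swapped(self) -> "FragmentPartition":
        """Partition with the fragment labels exchanged (B first)."""
        return FragmentPartition(
            self.n_orb_b, self.n_orb_a,
            {"A": self.n_elec["B"], "B": self.n_elec["A"]},
            {"A": self.ms2["B"], "B": self.ms2["A"]})


# ---------------------------------------------------------------------------
# FCIDUMP I/O


class FcidumpFormatError(ValueError):
    pass


def read_fcidump(path) -> ActiveSpaceHamiltonian:
    """Read an FCIDUMP file, restoring full 8-fold integral symmetry.

    The returned Hamiltonian carries the header's NELEC/MS2 as metadata.
    """
    with open(path) as fh:
        text = fh.read()
    m = re.search(r"&FCI(.*?)(/|&END)", text, re.S | re.I)
    if m is None:
        raise FcidumpFormatError("no &FCI namelist header found")
    header = m.group(1)

    def get_int(key, required=True, default=None):
        mm = re.search(rf"{key}\s*=\s*(-?\d+)", header, re.I)
        if mm is None:
            if required:
                raise FcidumpFormatError(f"{key} missing from header")
            return default
        return int(mm.group(1))

    n_orb = get_int("NORB")
    nelec = get_int("NELEC")
    ms2 = get_int("MS2", required=False, default=0)
    if n_orb < 1:
        raise FcidumpFormatError("NORB must be positive")

    h = np.zeros((n_orb, n_orb))
    g = np.zeros((n_orb, n_orb, n_orb, n_orb))
    e_core = 0.0
    body = text[m.end():]
    for line in body.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise FcidumpFormatError(f"malformed record: {line!r}")
        val = float(parts[0].replace("D", "E").replace("d", "e"))
        p, q, r, s = (int(x) for x in parts[1:])
        for idx in (p, q, r, s):
            if idx < 0 or idx > n_orb:
                raise FcidumpFormatError(f"index out of range: {line!r}")
        if p == q == r == s == 0:
            e_core = val
        elif r == 0 and s == 0:
            h[p - 1, q - 1] = val
            h[q - 1, p - 1] = val
        elif r != 0 and s != 0 and p != 0 and q != 0:
            i, j, k, l = p - 1, q - 1, r - 1, s - 1
            for a, b in ((i, j), (j, i)):
                for c, d in ((k, l), (l, k)):
                    g[a, b, c, d] = val
                    g[c, d, a, b] = val
        else:
            raise FcidumpFormatError(f"malformed record: {line!r}")
    return ActiveSpaceHamiltonian(n_orb, e_core, h, g, nelec=nelec, ms2=ms2)


def write_fcidump(ham: ActiveSpaceHamiltonian, path, nelec=None, ms2=None,
                  tol=1e-14):
    """Write the unique nonzero integrals of ``ham`` in FCIDUMP format."""
    n = ham.n_orb
    if nelec is None:
        nelec = ham.nelec if ham.nelec is not None else n
    if ms2 is None:
        ms2 = ham.ms2 if ham.ms2 is not None else 0
    lines = [f" &FCI NORB={n},NELEC={nelec},MS2={ms2},",
             "  ORBSYM=" + "1," * n,
             "  ISYM=1,",
             " &END"]
    seen = set()
    for p in range(n):
        for q in range(p + 1):
            for r in range(n):
                for s in range(r + 1):
                    if (p, q) < (r, s):
                        continue
                    key = (p, q, r, s)
                    if key in seen:
                        continue
                    seen.add(key)
                    val = ham.g[p, q, r, s]
                    if abs(val) > tol:
                        lines.append(f"{val:23.16E} {p+1:4d} {q+1:4d} "
                                     f"{r+1:4d} {s+1:4d}")
    for p in range(n):
        for q in range(p + 1):
            if abs(ham.h[p, q]) > tol:
                lines.append(f"{ham.h[p,q]:23.16E} {p+1:4d} {q+1:4d} "
                             f"   0    0")
    lines.append(f"{ham.e_core:23.16E}    0    0    0    0")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Partition file I/O
#
# Format: two header lines "<label> <n_elec> <ms2>" (A first), then one line
# per active orbital "<index> <label>" with 0-based indices, A block first.


def write_partition(part: FragmentPartition, path):
    lines = ["# fragment partition: label n_elec ms2; then orbital label"]
    for lab in ("A", "B"):
        lines.append(f"{lab} {part.n_elec[lab]} {part.ms2[lab]}")
    for p in range(part.n_orb):
        lines.append(f"{p} {part.fragment_of(p)}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_partition(path) -> FragmentPartition:
    n_elec, ms2 = {}, {}
    labels = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#")[0].strip()
            if not line:
                continue
            parts = line.split()
            if parts[0] in ("A", "B") and len(parts) == 3:
                n_elec[parts[0]] = int(parts[1])
                ms2[parts[0]] = int(parts[2])
            elif len(parts) == 2:
                labels[int(parts[0])] = parts[1]
            else:
                raise ValueError(f"malformed partition line: {raw!r}")
    if set(n_elec) != {"A", "B"}:
        raise ValueError("partition file must declare fragments A and B")
    n_orb = len(labels)
    if sorted(labels) != list(range(n_orb)):
        raise ValueError("orbital indices must cover 0..n_orb-1")
    seq = [labels[p] for p in range(n_orb)]
    n_a = seq.count("A")
    if seq != ["A"] * n_a + ["B"] * (n_orb - n_a):
        raise ValueError("all A orbitals must precede all B orbitals")
    return FragmentPartition(n_a, n_orb - n_a, n_elec, ms2)
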