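"""Gaussian basis sets generated from the classic Slater-fit construction.

``sto-3g`` is produced exactly the way the standard tables were made: the
least-squares three-Gaussian fits to Slater 1s and 2s/2p functions at unit
exponent, with exponents scaled by the standard per-element zeta factors
(alpha -> alpha * zeta**2, coefficients unchanged for normalized primitives).

``svf`` ("split-valence fit") is a package-defined double-zeta-quality set
built from the same primitives: the core function stays contracted, each
valence function is split into an inner contracted part (two tightest
primitives) and a free outer primitive.  It is *not* one of the standard
split-valence sets; it exists so that scans can probe basis-set flexibility
without external data.

Only s and p shells are provided (all elements used here are H, C, N, O).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Shell", "build_basis", "ELEMENT_Z"]

ELEMENT_Z = {"H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
             "O": 8, "F": 9, "Ne": 10}

# three-Gaussian least-squares fits to Slater functions with zeta = 1
_STO3G_1S_EXP = np.array([2.227660584, 0.405771156, 0.109818])
_STO3G_1S_COEF = np.array([0.154328967, 0.535328142, 0.444634542])
_STO3G_2SP_EXP = np.array([0.994203, 0.231031, 0.0751386])
_STO3G_2S_COEF = np.array([-0.09996723, 0.39951283, 0.70011547])
_STO3G_2P_COEF = np.array([0.15591627, 0.60768372, 0.39195739])

# standard Slater-exponent scale factors (zeta) per element and shell
_ZETA = {
    "H": {"1s": 1.24},
    "He": {"1s": 1.69},
    "Li": {"1s": 2.69, "2sp": 0.80},
    "Be": {"1s": 3.68, "2sp": 1.15},
    "B": {"1s": 4.68, "2sp": 1.45},
    "C": {"1s": 5.67, "2sp": 1.72},
    "N": {"1s": 6.67, "2sp": 1.95},
    "O": {"1s": 7.66, "2sp": 2.25},
    "F": {"1s": 8.65, "2sp": 2.55},
}


@dataclass
class Shell:
    """One contracted shell: angular momentum, center, primitives."""

    l: int
    center: np.ndarray          # (3,), bohr
    exps: np.ndarray            # (K,)
    coefs: np.ndarray           # (K,) coefficients of *normalized* primitives
    atom_index: int

    @property
    def n_comp(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def _df(k: int) -> float:
    """(2k-1)!!"""
    out = 1.0
    for i in range(2 * k - 1, 0, -2):
        out *= i
    return out


def prim_norm(alpha: float, l: int) -> float:
    """Norm of a Cartesian primitive with lx=l, ly=lz=0."""
    return ((2 * alpha / np.pi) ** 0.75
            * (4 * alpha) ** (l / 2.0) / np.sqrt(_df(l)))


def component_factors(l: int) -> np.ndarray:
    """Per-component norm ratio relative to the (l,0,0) component."""
    comps = cartesian_components(l)
    return np.array([np.sqrt(_df(l) / (_df(a) * _df(b) * _df(c)))
                     for a, b, c in comps])


def cartesian_components(l: int):
    out = []
    for a in range(l, -1, -1):
        for b in range(l - a, -1, -1):
            out.append((a, b, l - a - b))
    return out


def _normalized_shell(l, center, exps, coefs, atom_index) -> Shell:
    """Shell with coefficients rescaled to unit contracted self-overlap."""
    exps = np.asarray(exps, float)
    coefs = np.asarray(coefs, float)
    # self-overlap of the (l,0,0) contracted component
    s = 0.0
    for i in range(len(exps)):
        for j in range(len(exps)):
            p = exps[i] + exps[j]
            sij = (np.pi / p) ** 1.5 * _df(l) / (2 * p) ** l
            s += (coefs[i] * prim_norm(exps[i], l)
                  * coefs[j] * prim_norm(exps[j], l) * sij)
    return Shell(l, np.asarray(center, float), exps, coefs / np.sqrt(s),
                 atom_index)


def _element_shells(sym: str, name: str):
    """(l, exps, coefs) tuples of one element in the requested basis."""
    z = _ZETA.get(sym)
    if z is None:
        raise ValueError(f"no basis data for element {sym}")
    shells = []
    e1 = _STO3G_1S_EXP * z["1s"] ** 2
    if name == "sto-3g":
        shells.append((0, e1, _STO3G_1S_COEF))
        if "2sp" in z:
            e2 = _STO3G_2SP_EXP * z["2sp"] ** 2
            shells.append((0, e2, _STO3G_2S_COEF))
            shells.append((1, e2, _STO3G_2P_COEF))
        return shells
    if name == "svf":
        if "2sp" not in z:      # hydrogen-like: split the 1s itself
            shells.append((0, e1[:2], _STO3G_1S_COEF[:2]))
            shells.append((0, e1[2:], np.array([1.0])))
            return shells
        shells.append((0, e1, _STO3G_1S_COEF))
        e2 = _STO3G_2SP_EXP * z["2sp"] ** 2
        shells.append((0, e2[:2], _STO3G_2S_COEF[:2]))
        shells.append((0, e2[2:], np.array([1.0])))
        shells.append((1, e2[:2], _STO3G_2P_COEF[:2]))
        shells.append((1, e2[2:], np.array([1.0])))
        return shells
    raise ValueError(f"unknown basis {name!r} (available: sto-3g, svf)")


def build_basis(symbols, coords_bohr, name: str = "sto-3g"):
    """List of normalized Shells for a molecule (coordinates in bohr)."""
    shells = []
    for ia, (sym, xyz) in enumerate(zip(symbols, coords_bohr)):
        for l, exps, coefs in _element_shells(sym, name.lower()):
            shells.append(_normalized_shell(l, xyz, exps, coefs, ia))
    return shells
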