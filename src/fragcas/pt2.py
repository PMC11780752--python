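"""Channel-resolved second-order perturbation theory on the product state.

For each interaction channel ``H'_c = sum_mn g_mn O^A_m O^B_n`` the
perturbing basis is the partially contracted family

    ``|Phi_mn> = O^A_m O^B_n |Psi0>``,

stored implicitly as pairs of fragment sector vectors ``(O^A_m psi_A,
O^B_n psi_B)``.  Because the zeroth-order Hamiltonian is a sum of fragment
operators plus a scalar, every matrix element factorizes over fragments:

    ``S = <x_A|x_A'> <x_B|x_B'>``
    ``M - e0 S = <x_A|(H_A^eff - E_A)|x_A'> <x_B|x_B'>
               + <x_A|x_A'> <x_B|(H_B^eff - E_B)|x_B'>``

and the right-hand side is ``V = S g``.  The linear system
``(M - e0 S) C = -V`` is solved per sector block after canonical
orthogonalization of the overlap metric; ``e2 = V . C <= 0``.

Fermionic phases from commuting B-operators past the A fragment are uniform
within a channel (|O_B| has fixed parity and the reference fragment electron
number is sharp), so they cancel in S and M and enter V and C as a global
sign that drops out of ``e2``; they are therefore omitted here.  The dense
oracle validates this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import ci
from .decompose import CHANNELS, HamiltonianDecomposition
from .embedding import ProductState, sector_matrix

__all__ = ["PT2Result", "ChannelResult", "build_perturbing_basis",
           "solve_channel", "pt2_energies", "first_order_check"]

log = logging.getLogger(__name__)


@dataclass
class BasisBlock:
    """Members of one (sector_A, sector_B) block of a perturbing basis."""

    sector_a: ci.Sector
    sector_b: ci.Sector
    x_a: np.ndarray        # (m, dim_A) applied fragment-A vectors
    x_b: np.ndarray        # (m, dim_B)
    g: np.ndarray          # (m,) coefficients


@dataclass
class ChannelResult:
    channel: str
    e2: float
    n_members: int
    n_kept: int
    min_metric_eig: float
    min_h0_eig: float
    residual: float
    posdef_warning: bool = False
    amplitudes: list = field(default_factory=list)


@dataclass
class PT2Result:
    channels: dict
    e0: float
    e2_total: float
    e_total: float
    first_order: dict

    def e2(self, name: str) -> float:
        return self.channels[name].e2


def build_perturbing_basis(decomp: HamiltonianDecomposition,
                           psi0: ProductState, channel: str,
                           norm_cut: float = 1e-12):
    """Apply each channel term to the reference, grouped by target sectors.

    Zero-norm members (operators annihilating the reference) are dropped;
    they carry no weight in either the basis or the right-hand side.
    """
    blocks: dict = {}
    psi_a, psi_b = psi0.psi_a, psi0.psi_b
    for term in decomp.channels[channel]:
        res_a = ci.apply_ops(psi_a.ci, psi_a.sector, term.ops_a)
        res_b = ci.apply_ops(psi_b.ci, psi_b.sector, term.ops_b)
        if res_a is None or res_b is None:
            continue
        xa, sec_a = res_a
        xb, sec_b = res_b
        if np.linalg.norm(xa) * np.linalg.norm(xb) < norm_cut:
            continue
        key = (sec_a.key, sec_b.key)
        blocks.setdefault(key, []).append((xa, xb, term.coeff))
    out = []
    for (ka, kb), members in blocks.items():
        out.append(BasisBlock(
            ci.get_sector(*ka), ci.get_sector(*kb),
            np.array([m[0] for m in members]),
            np.array([m[1] for m in members]),
            np.array([m[2] for m in members])))
    return out


def _heff_dense(decomp, label, sector: ci.Sector) -> np.ndarray:
    h_eff = decomp.h_eff_spin(label)
    g_loc = decomp.g_local(label)
    m = sector_matrix(h_eff, g_loc, sector)
    return m.toarray() if sp.issparse(m) else np.asarray(m)


def assemble_matrices(block: BasisBlock, decomp: HamiltonianDecomposition,
                      psi0: ProductState):
    """(S, M_rel, V) of one block; ``M_rel = M - e0 S`` by construction."""
    e_a = _fragment_eff_energy(decomp, "A", psi0)
    e_b = _fragment_eff_energy(decomp, "B", psi0)
    ha = _heff_dense(decomp, "A", block.sector_a)
    hb = _heff_dense(decomp, "B", block.sector_b)
    s_a = block.x_a @ block.x_a.T
    s_b = block.x_b @ block.x_b.T
    m_a = block.x_a @ ha @ block.x_a.T
    m_b = block.x_b @ hb @ block.x_b.T
    S = s_a * s_b
    M_rel = (m_a - e_a * s_a) * s_b + s_a * (m_b - e_b * s_b)
    V = S @ block.g
    return S, M_rel, V


def _fragment_eff_energy(decomp, label, psi0: ProductState) -> float:
    psi = psi0.psi_a if label == "A" else psi0.psi_b
    h = _heff_dense(decomp, label, psi.sector)
    return float(psi.ci @ h @ psi.ci)


def solve_amplitudes(S, M_rel, V, metric_threshold: float = 1e-10):
    """Solve ``M_rel C = -V`` in the canonically orthogonalized metric.

    Returns (C, diagnostics).  Metric eigenvalues below
    ``metric_threshold * max_eig`` are discarded; a non-positive-definite
    projected ``M_rel`` is reported (intruder-state-like behaviour) but the
    solve proceeds.
    """
    import scipy.linalg as sla
    evals, U = np.linalg.eigh(S)
    if len(evals) == 0 or evals[-1] <= 0:
        return np.zeros(len(V)), {"kept": 0, "min_metric": 0.0,
                                  "min_h0": 0.0, "residual": 0.0,
                                  "posdef_warning": False}
    keep = evals > metric_threshold * evals[-1]
    X = U[:, keep] / np.sqrt(evals[keep])
    Mt = X.T @ M_rel @ X
    Mt = 0.5 * (Mt + Mt.T)
    Vt = X.T @ V
    # positive definiteness probed by Cholesky (cheap); the eigenvalue
    # spectrum is only computed on failure, to quantify the intrusion
    min_h0 = np.nan
    warn = False
    try:
        cf = sla.cho_factor(Mt)
        y = sla.cho_solve(cf, -Vt)
    except np.linalg.LinAlgError:
        me = np.linalg.eigvalsh(Mt)
        min_h0 = float(me[0])
        warn = True
        log.warning("projected H0 - e0 not positive definite "
                    "(lambda_min=%.3e): intruder-state-like behaviour",
                    min_h0)
        y = -np.linalg.pinv(Mt) @ Vt
    C = X @ y
    residual = float(np.linalg.norm(M_rel @ C + V))
    diag = {"kept": int(keep.sum()), "min_metric": float(evals[0]),
            "min_h0": min_h0, "residual": residual,
            "posdef_warning": warn}
    return C, diag


def channel_energy(C, V) -> float:
    """e2 of one block: C . V (non-positive up to roundoff)."""
    return float(C @ V)


def _flip(key):
    n, na, nb = key
    return (n, nb, na)


def solve_channel(decomp, psi0, channel, metric_threshold=1e-10,
                  exploit_spin_symmetry=True):
    """Per-channel e2 summed over sector blocks.

    For spin-unpolarized fragments (both Sz = 0) the global spin-flip maps
    each (sector_A, sector_B) block onto its Sz-reversed partner with
    identical matrices, so only one block per pair is solved and counted
    twice.
    """
    blocks = build_perturbing_basis(decomp, psi0, channel)
    spin_sym = (exploit_spin_symmetry
                and decomp.partition.ms2 == {"A": 0, "B": 0})
    keys = {(b.sector_a.key, b.sector_b.key) for b in blocks}
    weights = {}
    if spin_sym:
        for b in blocks:
            key = (b.sector_a.key, b.sector_b.key)
            fkey = (_flip(key[0]), _flip(key[1]))
            if fkey == key or fkey not in keys:
                weights[key] = 1.0
            elif fkey in weights and weights[fkey] == 2.0:
                weights[key] = 0.0
            else:
                weights[key] = 2.0
        blocks = [b for b in blocks
                  if weights[(b.sector_a.key, b.sector_b.key)] > 0]
    e2 = 0.0
    n_members = 0
    n_kept = 0
    min_metric = np.inf
    min_h0 = np.inf
    residual = 0.0
    warn = False
    amps = []
    for block in blocks:
        w = weights.get((block.sector_a.key, block.sector_b.key), 1.0)
        S, M_rel, V = assemble_matrices(block, decomp, psi0)
        C, diag = solve_amplitudes(S, M_rel, V, metric_threshold)
        e2 += w * channel_energy(C, V)
        n_members += len(V)
        n_kept += diag["kept"]
        min_metric = min(min_metric, diag["min_metric"])
        if not np.isnan(diag["min_h0"]):
            min_h0 = min(min_h0, diag["min_h0"])
        residual = max(residual, diag["residual"])
        warn = warn or diag["posdef_warning"]
        amps.append(C)
    if not blocks:
        min_metric = 0.0
        min_h0 = 0.0
    return ChannelResult(channel, e2, n_members, n_kept, float(min_metric),
                         float(min_h0), residual, warn, amps)


def first_order_check(decomp: HamiltonianDecomposition,
                      psi0: ProductState) -> dict:
    """Per-channel first-order energies <Psi0|H'_c|Psi0> (must vanish).

    Charge-transfer channels vanish by sector orthogonality; dispersion and
    the triplet-triplet channel by the fluctuation construction and sharp
    fragment Sz.
    """
    out = {}
    psi_a, psi_b = psi0.psi_a, psi0.psi_b
    for name in CHANNELS:
        val = 0.0
        for term in decomp.channels[name]:
            res_a = ci.apply_ops(psi_a.ci, psi_a.sector, term.ops_a)
            res_b = ci.apply_ops(psi_b.ci, psi_b.sector, term.ops_b)
            if res_a is None or res_b is None:
                continue
            xa, sec_a = res_a
            xb, sec_b = res_b
            if sec_a != psi_a.sector or sec_b != psi_b.sector:
                continue
            val += term.coeff * float(psi_a.ci @ xa) * float(psi_b.ci @ xb)
        out[name] = val
    return out


def pt2_energies(decomp: HamiltonianDecomposition, psi0: ProductState,
                 metric_threshold: float = 1e-10,
                 exploit_spin_symmetry: bool = True) -> PT2Result:
    """Per-channel and total second-order energies on the product state."""
    channels = {name: solve_channel(decomp, psi0, name, metric_threshold,
                                    exploit_spin_symmetry)
                for name in CHANNELS}
    e2_total = sum(c.e2 for c in channels.values())
    first = first_order_check(decomp, psi0)
    return PT2Result(channels, psi0.e0, e2_total, psi0.e0 + e2_total, first)
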