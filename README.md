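# fragcas

Two-fragment active-space embedding with channel-resolved second-order
perturbation theory.

## What problem this solves

Multiconfigurational (CAS) treatments of correlated molecules scale
exponentially with the active-space size.  When a molecule splits naturally
into two fragments — two stacked or covalently linked rings, two monomers
of a van-der-Waals dimer, the two halves of a polyene — most of the strong
correlation is *intra*fragment.  `fragcas` exploits that: each fragment
gets its own localized active space solved exactly (full CI), the
fragments see each other through a self-consistent mean field, and the
remaining *inter*fragment correlation is recovered perturbatively, resolved
into physically interpretable channels.  The cost is two CAS(n,m)
problems plus cheap linear algebra instead of one CAS(2n,2m) problem, and
the output tells you *what kind* of interaction binds the fragments.

It is a library for quantum-chemistry method developers and students:
everything is importable, inspectable and cross-checked against dense
brute-force oracles; a thin command-line interface (`fragcas`) covers the
file-based workflows.

## The model

For an active-space Hamiltonian
`H = E_core + Σ h_pq E_pq + ½ Σ (pq|rs)(E_pq E_rs − δ_qr E_ps)`
over orbitals split between fragments A and B, the package forms the exact
decomposition

    H = H_A + H_B + V_mf − shift
        + H_disp + H_1CT(A→B) + H_1CT(B→A) + H_2CT + H_TT

where `V_mf` is the Coulomb-minus-half-exchange mean field of each
fragment's 1-RDM and the channels collect, respectively, density
fluctuations (dispersion), one- and two-electron transfers (1CT, 2CT), and
the singlet-coupled product of local spin excitations (triplet–triplet,
TT).  The reference `|Ψ⁰⟩ = |Ψ_A⟩⊗|Ψ_B⟩` is the lowest-energy product of
fragment full-CI states with fixed local charge and Sz, found by
alternating fragment diagonalizations (energy `e0`, non-increasing by
construction).  Each channel `H'_c = Σ g_mn O^A_m O^B_n` then contributes

    e2_c = V·C,   (M − e0·S) C = −V,   Φ_mn = O^A_m O^B_n |Ψ⁰⟩

with every matrix element factorizing into fragment-local inner products
(`S = ⟨x_A|x'_A⟩⟨x_B|x'_B⟩`, similarly for `M` with the effective fragment
Hamiltonians inserted, `V = S·g`).  First-order corrections vanish
identically; every `e2_c ≤ 0`; and `E = e0 + Σ_c e2_c`.  See
`docs/methods.md` for the full derivation conventions, numerical choices
and limitations.

## Worked example

```python
from fragcas import ModelSpec, model_hamiltonian, oracle
from fragcas.decompose import decompose_hamiltonian, CHANNELS
from fragcas.embedding import self_consistent_product_state
from fragcas.pt2 import pt2_energies

ham, part = model_hamiltonian(ModelSpec(n_orb_a=3, n_orb_b=3,
                                        n_elec_a=2, n_elec_b=2,
                                        lam=0.15, seed=7))
ps = self_consistent_product_state(ham, part)
decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
res = pt2_energies(decomp, ps)
print(ps.e0, res.e_total, oracle.full_casci(ham, 4, 0))
```

prints (see `examples/seeded_model.py` for the annotated version):

```
product reference  e_ref   = -6.0720292673 Ha
embedded product   e0      = -6.1378183311 Ha
exact CASCI        e_exact = -6.1394464957 Ha

per-channel second-order energies (contracted vs uncontracted):
  dispersion -6.097e-05   -6.097e-05 Ha
  ct1_AtoB   -1.132e-03   -1.132e-03 Ha
  ct1_BtoA   -3.736e-04   -3.736e-04 Ha
  ct2        -3.791e-05   -3.791e-05 Ha
  tt         -9.187e-06   -9.187e-06 Ha

e0 + e2 = -6.1394321211 Ha
```

Reading this: the embedded product state already recovers most of the
correlation missing from the single-determinant reference (−6.072 →
−6.138 Ha against the exact −6.139 Ha); the perturbative channels close
most of the remaining gap, here dominated by single charge transfer; each
channel energy is non-positive and bounded below by its uncontracted
(exact first-order-space) counterpart.

Other examples: `examples/n2_dimer.py` (van-der-Waals dimer with a
CAS(6,6) triple-bond space per fragment and an exact CAS(12,12)
reference), `examples/butadiene_cut.py` (cutting a covalent bond; the
bridge bond/antibond pair is biased to the first fragment),
`examples/fcidump_workflow.py` (FCIDUMP + partition-file input, as used by
the CLI).

From a shell:

```sh
fragcas make-fixture --n-orb 3,3 --n-elec 2,2 --lam 0.15 --seed 7
fragcas run --fcidump model.fcidump --partition model.partition --oracle
fragcas scan --bond-right 1.2:2.0:0.4 --out scan.json   # N2 dimer scan
```

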