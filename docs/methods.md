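# Methods

## The model

`fragcas` treats a molecule whose active space splits naturally into two
spatially localized fragments A and B.  The active-space Hamiltonian in
chemists' notation,

    H = E_core + Σ_pq h_pq E_pq + ½ Σ_pqrs (pq|rs) (E_pq E_rs − δ_qr E_ps),

with spin-summed excitations `E_pq = Σ_σ a†_pσ a_qσ`, is decomposed exactly
into

    H = H_A + H_B + V_mf − shift
        + H_disp + H_1CT(A→B) + H_1CT(B→A) + H_2CT + H_TT.

`H_A`/`H_B` collect all terms whose orbital indices live on one fragment.
The number-conserving interfragment terms are products of one-body
operators; after fragment-normal reordering the Coulomb class couples
`E^A ⊗ E^B` and the exchange class contributes
`−(uy|xv) [ ½ E^A_uv E^B_xy + 2 S^A_uv · S^B_xy ]`, where `S_pq` is the
one-body spin-vector operator.  The spin-scalar parts are split by the
mean-field substitution `E → ⟨E⟩ + δE` into the one-body embedding
operators `V_mf` (a spin-resolved Coulomb-minus-half-exchange field), a
scalar double-counting `shift`, and the **dispersion** channel
`δE ⊗ δE`.  The spin-vector part forms the **triplet–triplet** (TT)
channel; its `Sz ⊗ Sz` piece is mean-subtracted the same way so that the
first-order energy vanishes even for spin-polarized fragments (for singlet
fragments the subtraction is identically zero).  Terms that move one or two
electrons between the fragments form the directional **single** and the
**double charge-transfer** channels; they are stored as canonically ordered
fermionic strings with every reordering parity absorbed into the
coefficient.  The decomposition is exact: rebuilding a dense matrix from
all parts reproduces the dense matrix of `H` to < 1e-10 (enforced in the
test suite on seeded models, including open-shell and asymmetric fillings).

## Reference product state

The zeroth-order state is the lowest-energy product
`|Ψ⁰⟩ = |Ψ_A⟩ ⊗ |Ψ_B⟩` with fixed per-fragment electron number and Sz.
It is found by alternating exact diagonalizations (full CI in the fragment
sector) of

    H_X^eff = H_X + V_X[γ_other],

each half-step minimizing the total product-state energy over one factor,
so the energy sequence is non-increasing.  The product energy is evaluated
as `e0 = E_core + ⟨H_A⟩ + ⟨H_B⟩ + E_int(γ_A, γ_B)` with the bilinear
mean-field coupling `E_int`; this equals `⟨Ψ⁰|H|Ψ⁰⟩` because every removed
term has zero mean on the product state.  Fragment spin is enforced as
fixed Sz (the solver works in Sz-conserving determinant sectors); total-S
purity is diagnosed, not enforced.

Convergence control: energy change below `tol_e` (default 1e-9 Ha) *and*
1-RDM change below `tol_rdm` (default 1e-7) — energy alone can mask
oscillation between degenerate solutions.  Optional RDM damping
`γ ← (1−d)γ_new + dγ_old`; on a non-monotone step at zero damping the
iteration restarts once with d = 0.5.  Initialization uses the aufbau
determinant of each fragment (diagonal of the local one-body matrix),
which also furnishes the product-determinant reference energy `e_ref`
(equal to the RHF energy when the active space comes from RHF orbitals).
Degenerate fragment ground states (gap < 1e-8) are logged as warnings; the
lowest root is taken with a deterministic phase fix (first significant CI
coefficient positive).

## Perturbation theory

For each channel `H'_c = Σ_mn g_mn O^A_m O^B_n` the perturbing basis is the
partially contracted family `|Φ_mn⟩ = O^A_m O^B_n |Ψ⁰⟩`, held implicitly as
pairs of fragment sector vectors.  Since `H⁰` is a sum of fragment
operators plus a scalar, all matrices factorize over fragments:

    S           = ⟨x_A|x'_A⟩ ⟨x_B|x'_B⟩
    M − e0·S    = ⟨x_A|(H_A^eff − E_A)|x'_A⟩ ⟨x_B|x'_B⟩
                + ⟨x_A|x'_A⟩ ⟨x_B|(H_B^eff − E_B)|x'_B⟩
    V           = S·g

The linear system `(M − e0·S) C = −V` is solved per (sector_A, sector_B)
block after canonical orthogonalization of the metric (relative threshold
1e-10, configurable); `e2 = V·C ≤ 0` per channel and `E_total = e0 + Σ e2`.
Matrix elements of `H⁰` are evaluated by applying the effective fragment
Hamiltonians to the sector vectors rather than contracting stored
high-order RDMs — mathematically identical and far cheaper at this scale.
The mean-field operators inside `H⁰` stay frozen at the converged RDMs in
charge-shifted sectors (`H⁰` is one fixed operator).

Contraction level: members are deduplicated canonical spin-orbital operator
pairs, a slightly finer contraction than a spin-adapted grouping; the
sector-blocked span, and hence every ordering invariant
(`e2_uncontracted ≤ e2_contracted ≤ 0`), is unaffected.  Fermionic phases
from commuting B-operators past fragment A are uniform within a channel
(fixed parity of |O_B|, sharp reference electron count), cancel in S and M
and drop out of `e2`; the dense oracle validates this.  The two 1CT
directions are computed separately and summed when a single 1CT number is
wanted.  For spin-unpolarized fragments the Sz-reversed sector blocks are
related by the global spin flip and carry identical matrices; one block per
pair is solved and counted twice (verified against the unpaired
computation).

A projected `H⁰ − e0` that is not positive definite (possible when charge
transfer is energetically downhill at mean-field level, an intruder-state
analogue) is reported with its lowest eigenvalue; the solve proceeds by
pseudo-inverse but the non-positivity invalidates the `e2 ≤ 0` guarantee
for that channel.

## Oracles

The brute-force references share no code with the factorized path beyond
the type definitions: the full Hamiltonian on the combined fragment-ordered
determinant basis is built elementwise from Slater–Condon rules; exact
CASCI uses a separate string-based direct-CI Davidson solver (dimension
853 776 for the dimer benchmark's CAS(12,12)); uncontracted PT2 solves the
dense resolvent equation in the orthogonal complement of `Ψ⁰`; the
contracted solve is cross-checked against a dense constrained minimization
of the Hylleraas functional over the same span.  The Gaussian integral
engine is validated against closed-form s-integral formulas and, for p
functions, against center-derivatives of those closed forms.

## Mean-field backend and basis sets

A compact restricted-Hartree–Fock backend (McMurchie–Davidson integrals
with numba kernels, DIIS, deterministic jittered restarts to avoid
aufbau-violating stationary points) supplies canonical orbitals, the Fock
matrix and AO integrals.  The bundled `sto-3g` basis is generated exactly
from its published construction — three-Gaussian least-squares fits to unit
Slater functions, scaled by the standard per-element zeta factors — and the
package-defined `svf` split-valence set reuses those primitives with the
valence split into an inner contracted and a free outer function.  `svf`
is *not* a standard basis; it exists to probe basis flexibility without
external data.  All bundled molecular results therefore refer to minimal
or split-valence quality; channel-structure statements (first-order zeros,
channel hierarchies, variational bounds) are basis-independent, absolute
correlation energies are not.

## Orbital localization and active spaces

Canonical MOs are localized by Pipek–Mezey Jacobi sweeps with gross
Mulliken *fragment* populations as the localization functional (occupied
and valence-virtual blocks separately; the bundled bases produce no hard
virtuals).  Orbitals go to the fragment with the larger population; an
orbital whose largest population is below 0.7 — a bond/antibond pair cut by
the fragmentation — is biased to the first fragment, which makes covalently
cut dimers well defined.  A clean localized orbital exceeds 0.9 in
practice while a σ bond across the cut sits near 0.5, so 0.7 separates the
two regimes.  Orbitals are then recanonicalized (Fock matrix
block-diagonalized per fragment block) and active spaces selected per
fragment by quasi-energy ordering; remaining occupied orbitals are folded
into a frozen core.  This is a deliberately simple top-down construction:
it preserves the occupied span exactly (tested) but defines valence
virtuals by count rather than by fragment reference calculations, so
quantitative comparisons with orbital sets built from intrinsic fragment
orbitals will differ.

## Benchmark systems and study conditions

* **N2 dimer** — two parallel N2 molecules, centers 2.0 Å apart, left bond
  1.2 Å, right bond scanned (desk scan 1.2/1.6/2.0 Å; full 13-point scan
  0.9–2.1 Å available through the CLI).  Active space: the triple-bond σ,
  π, π* and σ* orbitals, i.e. CAS(6,6) per fragment, CAS(12,12) combined —
  small enough that the exact CASCI reference is computed for every point.
  At equilibrium the perturbative correction is carried by dispersion and
  single charge transfer while 2CT and TT read as zero (|e2| ≲ 1e-5 Ha);
  under bond stretching 1CT dominates and TT grows to the mHa range
  because the stretched fragment develops low-lying triplet states — the
  same mechanism that makes TT important in dissociating polyenes.  The
  channels driven by interfragment exchange integrals (~1e-3 Ha at this
  separation) are small but not numerically zero; statements about their
  vanishing are resolution statements, not symmetry zeros.
* **Butadiene** — planar s-trans geometry from idealized bond parameters,
  cut through the middle C–C bond; the bridge σ and σ* localize with
  ~0.5/0.5 populations and are biased to fragment A.
* **Seeded models** — deterministic random two-fragment Hamiltonians with
  spread orbital levels, repulsive diagonal Coulomb integrals and all
  fragment-crossing integrals scaled by a coupling λ (plus a Hubbard-chain
  style).  Default λ = 0.15 with half-filled 2+2 and 3+3 fragments keeps
  charge-transfer gaps open (no intruders) while exercising every channel.
  These models emulate generic weakly coupled correlated fragments; they do
  not emulate basis-set or localization error, near-degenerate charge
  sectors, or more than two fragments, so passing them validates the
  operator algebra and the PT2 solver, not chemical accuracy.

## Numerical choices

* FCI sectors ≤ ~1600 determinants are diagonalized densely, larger ones
  with a Davidson solver (deterministic unit-vector start on the lowest
  diagonal); the fragment-solver dimension cap defaults to 1e6.
* Metric threshold 1e-10 (relative) for canonical orthogonalization,
  standard practice for near-linearly-dependent contracted bases.
* The exact-CASCI Davidson for the dimer is warm-started with the embedded
  product state (overlap ~0.99 near equilibrium).
* Degenerate inputs: zero-norm perturbing members are dropped (they carry
  no right-hand side); duplicated members are removed by the metric
  truncation (tested).
* Empty sectors (zero electrons) return the vacuum state with the scalar
  energy.

## Known limitations

Two fragments only; no orbital optimization of the product state; no
core/virtual (NEVPT2-like) excitations outside the combined active space;
restricted (closed-shell) mean-field reference; s/p basis functions only;
fragment spin fixed as Sz rather than total S.  Absolute energies carry
minimal-basis error by construction of the bundled basis sets.
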