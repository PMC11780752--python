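"""N2 dimer at equilibrium: fragment embedding plus channel-resolved PT2.

Two parallel N2 molecules 2.0 Angstrom apart, each contributing the six
triple-bond orbitals as a CAS(6,6) fragment active space.  Prints the
Hartree-Fock, embedded-product, perturbed and exact energies and the
decomposition of the interfragment correlation.  Takes a few minutes
(the exact reference diagonalizes a CAS(12,12) space of 853 776
determinants).
"""

from fragcas.pipeline import n2_dimer_point

rec, ps, decomp, extras = n2_dimer_point(bond_right=1.2, with_oracle=True)

print(f"E_HF      = {rec['e_hf']:.8f} Ha")
print(f"e0        = {rec['e0']:.8f} Ha   (embedded product state)")
print(f"e0 + e2   = {rec['e_total']:.8f} Ha")
print(f"E_exact   = {rec['e_exact']:.8f} Ha   (CASCI(12,12))")
print("\ninterfragment correlation by channel:")
for name, val in rec["e2"].items():
    print(f"  {name:10s} {val: .3e} Ha")
print(f"\nfirst-order residuals max: "
      f"{max(abs(v) for v in rec['first_order'].values()):.1e} Ha")
print("\nThe embedding captures the strong intrafragment (triple-bond) "
      "correlation missed by HF; the remaining interfragment correlation "
      "is dominated by dispersion and single charge transfer, while the "
      "double-charge-transfer and spin-exchange channels are negligible "
      "at this geometry.")
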