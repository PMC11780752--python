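"""Embedding + channel-resolved PT2 on a seeded two-fragment model.

Builds a deterministic random Hamiltonian (two 3-orbital fragments, two
electrons each, interfragment coupling 0.15), finds the mean-field-embedded
product state, recovers interfragment correlation per channel, and compares
against the exact and uncontracted references.
"""

import numpy as np

from fragcas import ModelSpec, model_hamiltonian, oracle
from fragcas.decompose import CHANNELS, decompose_hamiltonian
from fragcas.embedding import self_consistent_product_state
from fragcas.pt2 import pt2_energies

spec = ModelSpec(n_orb_a=3, n_orb_b=3, n_elec_a=2, n_elec_b=2,
                 lam=0.15, seed=7)
ham, part = model_hamiltonian(spec)

ps = self_consistent_product_state(ham, part)
decomp = decompose_hamiltonian(ham, part, ps.gamma_a, ps.gamma_b)
res = pt2_energies(decomp, ps)

e_exact = oracle.full_casci(ham, 4, 0)
e2_unc, _, _ = oracle.uncontracted_pt2(decomp, ps.psi_a, ps.psi_b)

print(f"product reference  e_ref   = {ps.e_ref:.10f} Ha")
print(f"embedded product   e0      = {ps.e0:.10f} Ha")
print(f"exact CASCI        e_exact = {e_exact:.10f} Ha")
print("\nper-channel second-order energies (contracted vs uncontracted):")
for name in CHANNELS:
    print(f"  {name:10s} {res.channels[name].e2: .3e}   "
          f"{e2_unc[name]: .3e} Ha")
print(f"\ne0 + e2 = {res.e_total:.10f} Ha")
print("Each channel e2 is <= 0 and lies between the uncontracted value and "
      "zero; e0 sits between e_exact and e_ref, and e0 + e2 moves toward "
      "e_exact.")
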