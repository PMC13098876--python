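"""Ac-225 decay-chain accounting and sphere S-values.

Expands the chain to stable Bi-209, counts alpha decays per parent
decay, and compares the parent-only and full-chain S-values for a
150 mg tumor sphere — the chain carries most of the dose.
"""

import spheredose as sd
from spheredose.nuclides import RadiationClass

chain = sd.build_chain("Ac-225")
print("member            decays per parent decay")
for sym, cb in chain.members:
    print(f"  {sym:8s}        {cb:.4f}")
print(f"terminal: {chain.terminal}")
print(f"alpha decays per Ac-225 decay: {sd.chain_alpha_count(chain):.3f}")

e_alpha = sd.chain_energy_per_decay(chain, {RadiationClass.ALPHA})
e_all = sd.chain_energy_per_decay(chain)
print(f"chain alpha energy: {e_alpha:.2f} MeV/decay (total {e_all:.2f})")

mass = 0.15  # g
s_parent = sd.s_value(sd.get_nuclide("Ac-225"), mass)
s_chain = sd.chain_s_value(chain, mass)
print(f"\n150 mg water sphere (r = {s_chain.radius_cm:.3f} cm):")
print(f"  Ac-225 alone : S = {s_parent.s_mgy_per_mbq_s:.4g} mGy/(MBq s)")
print(f"  full chain   : S = {s_chain.s_mgy_per_mbq_s:.4g} mGy/(MBq s) "
      f"({s_chain.s_mgy_per_mbq_s / s_parent.s_mgy_per_mbq_s:.1f}x)")
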