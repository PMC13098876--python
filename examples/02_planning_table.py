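"""Injected-activity planning from tumor dose coefficients.

Reproduces the worked products for the two melanoma tumors (dose
coefficients 21.1 and 87.4 Gy/uCi at 0.2 uCi injected), then inverts a
4 Gy / 15 Gy prescription pair and prints a small planning table.
"""

import spheredose as sd

for name, coeff in [("GD2- (B16)", 21.1), ("GD2+ (B78)", 87.4)]:
    dose = sd.dose_from_injected(coeff, 0.2)
    print(f"{name}: {coeff} Gy/uCi x 0.2 uCi = {dose:.3g} Gy")

print("\nPrescriptions against the GD2- coefficient (21.1 Gy/uCi):")
for gy in (4.0, 15.0):
    uci, mbq = sd.required_injected_activity(
        sd.Prescription("tumor", gy, tumor_mass_mg=150.0), 21.1
    )
    print(f"  {gy:>4} Gy -> {uci:.4g} uCi = {mbq:.4g} MBq")

# mass-dependent coefficients come from data; here a two-point model
model = [(50.0, 40.0), (200.0, 12.0)]  # (tumor mass mg, Gy/uCi)
table = sd.plan_table([50, 100, 150, 200], [2, 4, 8, 15], model)
print("\nRequired injected activity (uCi), rows = tumor mass (mg):")
print(table.to_frame("uci").round(4).to_string())
print("Cells grow along the dose axis and with tumor mass (smaller Gy/uCi).")
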