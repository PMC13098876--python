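"""ddCt fold changes of tumor genes vs an untreated Day-0 control group.

Builds a small Ct table in memory (duplicate wells per sample, Hprt as
the endogenous control) and reports 2^-ddCt per gene and group.
"""

import spheredose as sd

measurements = []
# untreated controls: Fas dCt = 5
for i in range(3):
    for _ in range(2):  # technical duplicates
        measurements.append(sd.CtMeasurement(f"c{i}", "day0", "Fas", 25.0 + 0.1 * i, 20.0))
# treated: Fas dCt = 3  ->  ddCt = -2  ->  fold 4
for i in range(3):
    for _ in range(2):
        measurements.append(sd.CtMeasurement(f"t{i}", "rpt_15gy", "Fas", 23.0 + 0.1 * i, 20.0))

table = sd.fold_change_table(measurements, control_group="day0")
print(table.to_string(index=False, float_format=lambda x: f"{x:.3g}"))
print("\nfold = 2^-ddCt: values > 1 mean the gene is upregulated after therapy")
print("relative to untreated tumors, normalized to the Hprt control per sample.")
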