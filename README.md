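# spheredose

Preclinical internal dosimetry and treatment planning for
radiopharmaceutical therapy (RPT), built around the MIRD schema with
organs modeled as unit-density liquid-water spheres. It takes per-organ
ex-vivo biodistribution time series (%IA/g, decay-corrected to injection
time), integrates them into cumulated activities, folds in full
decay-chain energy accounting (notably the four-alpha Ac-225 chain), and
returns absorbed-dose coefficients in Gy/MBq together with the injected
activity needed to hit a prescribed tumor dose.

It is aimed at preclinical nuclear-medicine groups running mouse
biodistribution/therapy studies with radiometal-labeled antibodies
(e.g. Ac-225-, Y-90- or Lu-177-labeled anti-GD2 constructs), plus a
small ΔΔCt module for the companion qPCR readouts.

## The model

For each organ with cumulated activity Ã (MBq·s per MBq injected) and
sphere S-value S (mGy/(MBq·s)), the absorbed-dose coefficient is

    D = Ã · S / 1000            [Gy/MBq injected]

- **Ã** is the trapezoidal integral of the whole-organ time–activity
  curve A(t)/A_inj = (%IA/g(t)/100) · m_organ · e^(−λ_phys t), with a
  physical-decay-only tail f(t_last)/λ_phys beyond the final timepoint.
- **S** for a sphere of mass m at density 1 g/cm³ is
  S = 10³ · Σ_i Δ_i · φ_i · 1.602×10⁻¹³ · 10⁶ / (m·10⁻³), with Δ_i the
  mean energy per decay of each radiation class (MeV) and φ_i its
  absorbed fraction (1 for charged particles, photons ignored by
  default).
- **Decay chains**: under the no-redistribution assumption each chain
  member decays in place with activity equal to the parent's times its
  cumulative branching, so chain S-values are branching-weighted member
  sums. The Ac-225 chain (Fr-221, At-217, Bi-213, Po-213/Tl-209,
  Pb-209 → stable Bi-209) carries ~4.8× the parent-only S-value.
- **Planning**: required injected activity = prescribed dose / D, in
  μCi and MBq (1 μCi = 0.037 MBq exactly).
- **ΔΔCt**: per-sample ΔCt = Ct(gene) − Ct(reference), ΔΔCt = mean
  ΔCt(treated) − mean ΔCt(control), fold = 2^(−ΔΔCt).

Nuclide half-lives, per-decay mean energies and branchings ship as a
human-readable fixture (`src/spheredose/data/nuclides.csv`) sourced from
standard nuclear-data compilations; nothing is downloaded at runtime.

## Worked example

```python
import spheredose as sd

# dose coefficients (Gy/uCi) known for two tumors; 0.2 uCi injected
sd.dose_from_injected(21.1, 0.2)   # -> 4.22 Gy
sd.dose_from_injected(87.4, 0.2)   # -> 17.48 Gy (17.5 to 3 s.f.)

# invert a prescription
sd.required_injected_activity(sd.Prescription("tumor", 4.22, 150.0), 21.1)
# -> (0.200 uCi, 0.0074 MBq)
```

End-to-end from a biodistribution (see `examples/01_dose_from_biodistribution.py`):

```
$ python examples/01_dose_from_biodistribution.py
simulated 96 measurements (8 organs x 4 timepoints x n=3)
       organ  mass_g  a_tilde_s  ...  s_mgy_per_mbq_s  dose_gy_per_mbq
tumor_gd2pos    0.15  4.818e+04  ...            30.05             1448
...
GD2+ tumor dose coefficient: 1447.8 Gy/MBq (closed-form truth 1388.1; rel. err 4.3%)
```

`a_tilde_s` is the cumulated activity in seconds; `dose_gy_per_mbq` is
the coefficient a prescription divides by. The generator's kinetics are
known in closed form, so the pipeline's recovery error is measurable —
here 4.3% on a noisy 4-timepoint design.

The other examples cover planning tables (`02`), decay-chain S-values
(`03`) and ΔΔCt fold changes (`04`). A thin CLI wraps the same library
calls: `spheredose simulate|dose|plan|qpcr|svalue --help`.

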