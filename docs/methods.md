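# Methods

## Scope and pipeline

spheredose implements organ-level internal dosimetry for preclinical
radiopharmaceutical therapy in the MIRD schema, specialized to the
setting of mouse biodistribution studies with radiometal-labeled
antibodies: serial ex-vivo %IA/g measurements, sphere self-dose
S-values, full decay-chain accounting, and inversion of dose
coefficients into injected-activity prescriptions. A companion ΔΔCt
module handles the qPCR readouts such studies collect, and a synthetic
generator provides datasets whose dose has a closed form so every stage
can be verified end to end.

Stages (each independently importable):

1. **biodist** — CSV reading/validation, replicate aggregation
   (mean ± SEM per organ and timepoint), exponential decay correction,
   secular-equilibrium Ac-225 quantification via Bi-213, allometric
   organ masses.
2. **tac** — whole-organ time–activity curves and trapezoid+tail
   cumulated activity Ã.
3. **svalue** — unit-density water-sphere S-values per nuclide or chain.
4. **dose** — Gy/MBq coefficients, worked doses, prescriptions, plan
   tables, and a pass-through hook for cross-organ contributions.
5. **qpcr** — 2^(−ΔΔCt) fold changes.
6. **simulate** — ground-truth biexponential kinetics generator.

## Conventions and units

- %IA/g (≡ %ID/g) inputs are decay-corrected to injection time; the
  physical factor e^(−λt) is re-applied exactly once, when the TAC is
  built. Supplying non-corrected values would double-count decay, so
  the convention is stated in the CSV docs.
- Times are reported in hours (the field's unit) and converted to
  seconds internally. Ã is in seconds (MBq·s/MBq), S in mGy/(MBq·s),
  doses in Gy, activities in μCi and MBq with the exact factor
  1 μCi = 0.037 MBq. Doses print to 3 significant figures, activities
  to 4.

## Nuclear data

Half-lives, per-decay mean energies Δ by radiation class (alpha, mean
beta, conversion electrons, photons; MeV/decay, yield-weighted over
lines), beta endpoints, daughters and branching fractions live in
`src/spheredose/data/nuclides.csv`, one row per emission class or
daughter edge, with the compilation recorded per row (ICRP 107-style
summary values). The Bi-213 fork (97.80% β→Po-213, 2.20% α→Tl-209) is
data, not code. Different compilations disagree at the percent level;
S-values inherit that uncertainty. The Δ convention uses
spectrum-averaged beta energies; endpoints (e.g. 2.28 MeV for Y-90) are
stored for reporting only.

Chains are expanded by a cycle-checked topological traversal of the
daughter graph; each member's cumulative branching is the sum over
paths of branch-fraction products. For Ac-225 this yields Fr-221,
At-217, Bi-213, Po-213 (0.978), Tl-209 (0.022), Pb-209, terminating at
Bi-209, and exactly 4 expected alpha decays per parent decay. Chain
energies and S-values assume secular equilibrium with no progeny
redistribution — each member decays where the parent does, at the
parent's rate times its cumulative branching. Pre-equilibrium
(Bateman) chain dosimetry is deliberately out of scope; a Bateman ODE
oracle in the test suite independently confirms that Bi-213 activity
reaches the branching-scaled parent activity within 1% after 10 Bi-213
half-lives, which is what justifies quantifying stored samples by their
Bi-213 gammas (the reader enforces a ≥10-half-life wait by default).

## Cumulated activity

The TAC is the measured per-gram uptake times organ mass times
e^(−λ_phys t). A (0, 0) anchor is prepended when the first measurement
is after injection — organ uptake of an IV antibody starts near zero.
For blood this underestimates the early integral, so
`anchor_mode="hold_first"` holds the first measured concentration back
to t = 0 instead. Integration is exact piecewise-linear trapezoid;
beyond the last sample only physical decay is assumed, adding
f(t_last)/λ_phys. A stable nuclide makes the tail infinite and is
rejected.

Two biases follow from the method itself and are documented rather than
corrected:

- **Discretization**: sparse grids under-integrate concave rises and
  over-integrate convex decays; on dense grids (≈600 points over 10
  physical half-lives, geometrically spaced early) the pipeline matches
  the analytic dose to <0.1% for Y-90, Lu-177 and the Ac-225 chain.
- **Tail overestimation**: real organs keep clearing biologically after
  the last timepoint, the tail does not. The inflation factor on the
  tail is ≈(λ_bio + λ_phys)/λ_phys, so it matters exactly when
  biological clearance is comparable to physical decay — for Ac-225
  (t½ 9.9 d) and a 168 h study the tail dominates Ã, and a
  fast-clearing organ's dose can be overestimated by tens of percent.
  For normal organs this is conservative (dose is overestimated); for
  tumors with persistent retention the bias is small.

## Sphere S-values

S = 10³ · Σ Δ_i·(1.602176634×10⁻¹³ J/MeV)·φ_i·10⁶ / (m·10⁻³ kg), for a
sphere of radius (3m/4πρ)^(1/3) at ρ = 1 g/cm³. Charged-particle
absorbed fraction defaults to 1 — an overestimate for high-endpoint
betas (Y-90, ~11 mm range) in sub-gram spheres; a `phi_charged` knob
exists but no escape model is supplied. Photons are ignored by default
(self-dose is charged-particle dominated for therapy nuclides); an
`analytic` mode applies φ = 1 − exp(−μ_en·r) at a representative
0.3 MeV μ_en as a labelled coarse approximation. With photons ignored,
S depends on mass only and scales exactly as 1/m.

## Planning

Dose coefficients are linear in Ã and injected activity, so a
prescription inverts to activity = dose/coefficient. Plan tables accept
either a constant coefficient or supplied (mass, coefficient) pairs
interpolated linearly; the mass dependence must come from data —
under mass-independent per-gram uptake a sphere coefficient is
mass-invariant, so the package refuses to invent one, and refuses to
extrapolate outside the supplied mass range without an explicit flag.
Cross-organ dose is a pass-through hook (source organ → Gy/MBq per unit
source Ã) contributing zero by default; no photon cross-fire physics is
bundled.

Published worked products used in tests: 21.1 and 87.4 Gy/μCi at
0.2 μCi give 4.22 and 17.5 Gy at 3 s.f. The companion pair 17.1 and
39.3 Gy/μCi compute to 3.42 and 7.86 Gy, while 3.41 and 7.87 Gy have
been quoted for them — a last-digit rounding inconsistency in the
source material, so only the first pair is machine-checked. Published
prescription tables (e.g. 1.369/5.217 MBq for 4/15 Gy) are treated as
data, not verification targets: the tumor masses behind them are
unavailable, and their internal 15/4 activity ratios (3.70–3.81)
confirm per-animal mass variation.

## Allometric organ masses

"Allometric" scaling is implemented as proportional (exponent-1)
scaling of a reference 20 g mouse organ-mass table shipped as an
editable fixture; the exponent is a keyword for sensitivity analysis.
Tumor masses are always user-supplied, never scaled.

## ΔΔCt

Per-sample ΔCt against the same-sample endogenous control (Hprt-style),
then group means, ΔΔCt = treated − control, fold = 2^(−ΔΔCt).
Technical duplicates are averaged at the Ct level per sample first.
Controls are pooled as one group mean. Amplification-efficiency
correction and downstream ANOVA are out of scope.

## Synthetic generator

Each organ follows u(t) = A·(e^(−λ_w t) − e^(−λ_u t)) in
decay-corrected %IA/g, so the physical Ã has the closed form
(A/100)·m·[1/(λ_w+λ_p) − 1/(λ_u+λ_p)] and the true dose is that times
the module's own chain S-value. Noise is multiplicative lognormal with
mean 1 (gamma counting of high-count samples is near-constant-CV),
default CV 10%. The default design is 8 organs {GD2+ tumor, GD2−
tumor, blood, liver, kidney, spleen, bone, muscle}, harvests at 3, 24,
72, 168 h, n = 3 per timepoint. (Study descriptions vary between 3 h
and 4 h for the first harvest; the reader accepts any positive first
timepoint and the generator uses 3 h.)

Default kinetics are illustrative shapes, not fits: blood rises within
the first hour (λ_u = 2/h) and clears at 0.015/h; tumors accumulate
over days (λ_u = 0.06/h) and retain essentially permanently
(λ_w = 2×10⁻⁴/h, biological t½ ≈ 144 d), matching the persistent
7-day tumor retention of residualizing radiometal-antibody conjugates.
Amplitudes (28 vs 9 %IA/g for GD2+/GD2− tumors, 30 for blood, 1.5–11
for normal organs) mimic antigen-specific targeting qualitatively.

What passing tests show: the pipeline arithmetic is correct to <0.1%
on dense noise-free data, and under the sparse 4-timepoint n = 3
design with 10% CV the recovered tumor dose has a median absolute
relative error of ~4–5% (asserted <10% over 200 seeded replicates),
with a stable positive bias from the physical-only tail. What they do
not show: accuracy for organs whose biological clearance rivals
physical decay (the tail bias there is a property of the
trapezoid+tail method, not of this implementation), real counting
statistics, partial-volume or imaging effects, or progeny
redistribution.

## Numerical choices

- Trapezoid integration is exact piecewise-linear (`numpy.trapezoid`);
  no adaptive quadrature, so results are bit-reproducible.
- Duplicate measurement times are averaged during aggregation; TACs
  require strictly increasing times.
- Lognormal noise uses σ² = ln(1+CV²), μ = −σ²/2 so the factor has
  mean exactly 1; generators are `numpy.random.default_rng(seed)`.
- Branching closure, chain breakdown sums and unit round-trips are
  enforced at 1e−9 relative or better; decay-constant/half-life
  consistency at 1e−12.
- Acceptance reruns use seeds derived as (seed·100003 + i) mod 2³¹.

## Known limitations

- Self-dose only; cross-organ dose requires a user-supplied table.
- φ = 1 for charged particles regardless of sphere size.
- No TAC model fitting or single-timepoint estimation; measured points
  are integrated directly.
- Organ-level only — no voxel dosimetry or microdosimetry.
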