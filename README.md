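# bilayerkit

Quantitative analysis of the four assay families used to characterize how
amphiphilic cations (imidazolium ionic liquids such as [C₁₂MIM]⁺Br⁻) perturb
phospholipid membranes with varying cholesterol content:

1. **Dye-leakage kinetics** — calcein release from vesicles, normalized as
   `% leakage(t) = 100 (Iₜ − I₀,ₜ)/(I_max,t − I₀,ₜ)` and fitted with the
   sigmoid `a₀ / (1 + e^{−(t−t_c)·k})`, giving the plateau a₀ (%), rate
   constant k (min⁻¹) and half-leakage time t_c (min).
2. **FRET lipid mixing** — NBD dequenching on probe dilution, read at 10 min
   with a ×1.5 correction of the post-Triton reference intensity.
3. **Solid-state NMR order analysis** — static ²H powder spectra of
   perdeuterated chains are dePaked (regularized inversion of the powder
   kernel), converted to smoothed order-parameter profiles |S_CD|(n) via the
   cumulative deuteron-weighted assignment, and summarized as the average
   order ⟨S⟩ and the first-order mean-torque chain extent L_c*; ³¹P spectra
   are fitted with an axially symmetric powder line shape for the chemical
   shift anisotropy Δσ (ppm).
4. **Langmuir monolayer thermodynamics** — from π(A) compression isotherms:
   lift-off area, compressional modulus `Cₛ⁻¹ = −A (∂π/∂A)_T`, and the
   excess Gibbs free energy of mixing
   `ΔG_exc = ∫ (A₁₂ − χ₁A₁ − χ₂A₂) dπ` over 0–30 mN/m.

No raw instrument data accompany the published tables, so every analysis is
paired with a seeded synthetic-data generator (`bilayerkit.synthetic`) whose
ground truth makes each stage verifiable by parameter recovery: generate
noiselessly with the published values, analyse, and compare.

## Worked example

```python
import bilayerkit as bk

spec = bk.LeakageTraceSpec(a0=99.1, k=0.52, tc=0.87, t_end=40.0)
leakage = bk.normalize_leakage(*bk.gen_leakage_traces(spec))
fit = bk.fit_sigmoid(leakage)
print(fit.a0, fit.k, fit.tc)   # 99.10, 0.519, 0.866
```

The refit recovers the generating plateau to 0.002 %, and the rate and
half-time to a few tenths of a percent (the small bias is the three-point
smoothing applied before fitting, switchable with `smooth=False`).
`examples/` holds one short script per capability — leakage kinetics, lipid
mixing, the ²H/³¹P pipeline, and monolayer thermodynamics — each printing
the recovered numbers next to their ground truth; the output above and in
those scripts is what the code actually prints.

A thin CLI wraps the same functions:

```bash
bilayerkit simulate leakage --config leak.yaml --out leak.csv
bilayerkit fit leakage --sample s.csv --baseline b.csv --triton t.csv
bilayerkit nmr profile --in pake.csv --carbons 15
bilayerkit monolayer liftoff --in iso.csv
bilayerkit reproduce --table 2
```

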