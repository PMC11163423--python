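# Methods

This note records the models the package implements, the numerical choices
behind them, and what the synthetic generators do and do not emulate.

## Leakage and mixing kinetics

Percent dye leakage is the pointwise normalization
`100 (Iₜ − I₀,ₜ)/(I_max,t − I₀,ₜ)` of the sample trace between the
no-additive baseline and the Triton-lysed reference. Values are *not*
clipped to [0, 100]; small negative excursions are reported for quality
control. Normalization is exactly invariant under a common affine rescaling
(gain/offset) of all three channels.

The kinetic model is the three-parameter sigmoid
`a₀ / (1 + e^{−(t−t_c)·k})` fitted by unweighted nonlinear least squares
(lmfit/Levenberg–Marquardt) with bounds a₀ ∈ [0, 110] %, k ∈ [0, 50] min⁻¹,
t_c ∈ [0, t_end], and initial guesses a₀ = max, t_c = time of half-max,
k = 4/(t₉₀ − t₁₀). By default the series is three-point smoothed before
fitting (the assay's plotting convention); this biases recovered
parameters by a few tenths of a percent on sharply rising traces, and
`smooth=False` fits the raw series, which recovers noiseless generator
output to better than 10⁻⁴ relative.

**Non-identifiability ("N.D.")**: a trace whose dynamic range is below 2 %
of its level, whose fitted half-time falls outside the sampled window, or
whose rate is pinned at a bound (Wald interval of k spanning the bound) is
reported with `converged=False` and NaN for k and t_c while a₀ still gives
the plateau — the situation where the kinetics are too fast or too slow to
resolve at a 30 s dead time. The Wald check approximates a
profile-likelihood criterion and is cheap enough to run on every fit.

Lipid mixing is a single-time-point normalization at the 10 min read with
the observed post-Triton intensity multiplied by 1.5 (a parameter, not a
constant): Triton suppresses NBD-PE fluorescence, so the observed
reference underestimates the true maximum.

## ²H and ³¹P solid-state NMR

**Conventions** (defined once in `constants.py`): the 90°-edge splitting of
a Pake doublet is (3/4)·χ_q·|S_CD| with the static quadrupolar coupling
χ_q = 167 kHz by default (configurable — a conventional C–D value, not a
fitted one). One transition of a doublet with edge splitting d sits at
ν(θ) = d(3cos²θ − 1)/2; since u = cos θ is uniform over a powder, the
transition's CDF is simply u(ν) = √((2ν/d + 1)/3) on [−d/2, d]. All
analysis-side line shapes are built from this closed form by CDF
differences over axis bins, which integrates the edge singularity exactly.

The *generator* instead powder-averages on a uniform θ grid with sin θ
weights (n_θ = 2000 by default), validated in the tests against the closed
form — keeping the forward model and the inversion kernel on distinct
numerical routes. Spectra are convolved with a unit-area Lorentzian
(half-width `broadening`) and normalized so the integral equals the total
deuteron count (CD₂ = 2, CD₃ = 3 per carbon).

**dePakeing** solves the linear inversion P(ν) = Σ_j K(ν; d_j) f_j for
f ≥ 0 by non-negative least squares with Tikhonov regularization (300
splitting bins up to the axis edge by default). The regularization weight
is chosen by the L-curve corner of an SVD ridge scan (25 log-spaced values,
maximum-curvature corner), then applied once in the augmented NNLS solve.
This discrete regularized inversion replaces the classical iterative
dePakeing scheme; the output contract is the same (oriented-sample
splitting distribution) and it is directly verifiable against the forward
oracle. Asymmetric inputs beyond 5 % are warned about and symmetrized.

**Smoothed profiles** assume splittings decrease monotonically from the
plateau (carbon 2) to the terminal methyl. Carbons are assigned by
cumulative deuteron-weighted spectral fraction, reading |S_CD| at the
midpoint quantile of each carbon's deuteron band counting from the largest
splitting. ⟨S⟩ is the unweighted per-carbon mean (a deuteron-weighted
variant sits behind `deuteron_weighted=True`); whether the two C2
deuterons should be treated separately is not resolvable from a powder
spectrum at this resolution, so C2 is one CD₂ band like the rest.

**Chain extent** uses the first-order mean-torque mapping per segment,
⟨cos β⟩ = ½(1 + √((8|S| − 1)/3)) for |S| ≥ 1/8, anchored at the all-trans
limit (|S| = 0.5 → 1.27 Å per segment, 19.05 Å for 15 segments). Below the
|S| = 1/8 branch point the first-order form leaves its real domain and is
replaced by the linear fallback ⟨cos β⟩ = 0.5 + |S|; the two branches do
not join continuously at 1/8, a known blemish of the truncated model that
only affects methyl-region carbons with very low order.

**³¹P CSA**: σ(θ) = σ_iso + Δσ(3cos²θ − 1)/3, so the pattern spans exactly
|Δσ| with the 90° edge (peak) at σ_iso − Δσ/3 and the 0° shoulder at
σ_iso + 2Δσ/3. `estimate_csa` least-squares fits the broadened closed-form
pattern over (Δσ, σ_⊥, broadening, amplitude), trying both pattern
orientations and reporting Δσ as a magnitude, as is conventional for
lamellar-phase widths.

## Monolayer thermodynamics

The compressional modulus −A(∂π/∂A)_T uses a Savitzky–Golay local-quadratic
derivative (window 11, one-sided endpoint stencils; a windowed polyfit for
non-uniform grids). It agrees with analytic derivatives of the generator
law to < 1 % away from the endpoints.

ΔG_exc integrates A₁₂ − χ₁A₁ − χ₂A₂ over a common pressure grid (trapezoid,
601 points over [0, 30] mN/m by default, both bounds configurable). A(π)
interpolation first projects non-monotone pressure segments (noise) to
monotone with a warning and keeps, for each held pressure level, the
smallest area — so A(0) is the lift-off area. The single unit constant
1 (Å²/molecule)(mN/m) = 10⁻²³ N_A J/mol ≈ 6.022 × 10⁻³ kJ/mol lives in
`constants.py`. The published ternary lipid/Chol/IL systems are treated
pseudo-binary (lipid+Chol as one component vs IL) when needed; the
operation itself is strictly binary.

**Lift-off detection**: baseline = median π over the largest-area decile;
the crossing of baseline + threshold (default 0.5 mN/m, configurable) is
located on a lightly smoothed trace, then sharpened by a segmented fit
π = b + c·(A₀ − A) + q·(A₀ − A)² past the kink, over the flat region plus
the rise arc up to baseline + 4×threshold. The quadratic term absorbs the
arc curvature, so the kink is recovered to within one 0.1 Å grid step on
noiseless isotherms; a raw threshold crossing (refine=False) would land
systematically a few Å² below the true onset for any smooth rise. Under
pressure noise of threshold/5 the estimate typically moves by about one
grid step, occasionally a few.

## Synthetic generators: what they emulate and what they don't

Generators cover: sigmoidal leakage with baseline/Triton channels starting
at the 30 s dead time; saturating NBD dequenching traces pinned to f_max at
the read point; deuteron-weighted Pake superpositions from monotone
profiles; axially symmetric CSA patterns; and smooth LE→LC isotherms
π(A) = π_c(x + s·x³)/(1 + s) in x = (A₀ − A)/(A₀ − A_end) with a sharp
lift-off at A₀, no coexistence plateau (the unsaturated-lipid case), and
exact area-additivity-plus-excess construction for binary mixtures, which
makes ΔG_exc testable with known ground truth. Noise is additive Gaussian
on intensities/pressures, seeded through `numpy.random.default_rng`;
identical seeds give bit-identical outputs.

Not emulated: photobleaching, instrument baseline roll or phase errors,
relaxation effects, MAS sidebands, compression-rate hysteresis, collapse
thermodynamics. Passing round trips therefore demonstrate correctness of
the inverse analyses under the stated forward models — not robustness to
instrument artifacts absent from those models.

**Default problem sizes** (also used by the acceptance script): leakage
traces at 0.1 min sampling (≈400–800 points), ²H spectra of 2048 points
over 250 kHz with 0.5 kHz broadening, ³¹P patterns of 1024 points with
1 ppm broadening, isotherms on a 0.1 Å² grid. At these sizes the full ²H
round trip runs in well under a second and the whole acceptance script in
a few seconds; recovery accuracy is limited by bin resolution, not sample
size.

## Known limitations

* The dePake inversion assumes the axis is uniform and the splitting grid
  resolution matches the question asked of it; heavily overlapped doublets
  are resolved only through the monotone-profile assumption, as in any
  smoothed-profile treatment.
* The mean-torque chain extent is a first-order model; its discontinuous
  low-order fallback is documented above.
* ΔG_exc accuracy depends on all three isotherms covering the full pressure
  range; the coverage check refuses to extrapolate.
* The sigmoid fit reports Wald standard errors; for strongly correlated
  (a₀, k, t_c) near non-identifiability these understate uncertainty, which
  is why the N.D. flag, not the standard error, gates reporting.
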