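# Methods

## Measurement model and units

Spectra are fractions in [0, 1] on an inclusive 400–700 nm grid at 1 nm
resolution (301 bands). The absorbed fraction is defined radiometrically,
A = 1 − (R + T); it is a flux balance, not a log₁₀ optical density, and
is always derived from the stored R and T rather than persisted, so the
three channels cannot drift apart. Files whose values exceed 1.5 are
rejected as percent-scaled rather than silently rescaled. Sensor noise
can push R + T slightly above 1; an excess up to 0.02 is tolerated (A is
clipped at 0 and the clip counted), anything larger flags the record as
physically inconsistent.

## Extract quantification

Pigment concentrations in the 80%-acetone extract follow the
Lichtenthaler linear equations in mg L⁻¹ from absorbances at 663, 646
and 470 nm; the per-area form is

    mg m⁻² = mg L⁻¹ × volume(mL) × Fd / 1000 / area(m²),

with g m⁻² (= mg m⁻²/1000) the canonical reporting unit. The total
chlorophyll equation is coefficient-identical to the sum of the a and b
equations (12.25 − 5.10 = 7.15, 21.50 − 2.79 = 18.71), which the suite
checks as an exact property. Negative concentrations from pathological
inputs are flagged, never clamped, so assay or simulation errors stay
visible. The 2×2 chlorophyll system is inverted exactly for simulation;
solutions outside the 0–1 absorbance range raise with a
dilution-adjustment hint. The leaf-area boundary takes m²; a cm²
convenience constructor covers the standard 2 cm² punch.

## Synthetic population

No spectra from the emulated study are available, so a forward generator
defines the study conditions: n = 150 leaves, half grown in full sun and
half in deep shade, measured on the 301-band grid, with a wet-lab
reference assay per leaf (2 cm² punch in 10 mL, Fd = 1, hence
mg L⁻¹ = 20 × g m⁻²).

True pigment contents: sun leaves draw Chl a ~ U(0.25, 0.46) g m⁻²,
shade leaves U(0.13, 0.30); Chl b is Chl a × U(0.33, 0.48) and
carotenoids (Chl a + Chl b) × U(0.20, 0.28); each marginal is clipped
into the published population range (Chl a 0.13–0.46, Chl b 0.058–0.19,
Car 0.033–0.16 g m⁻²). Total chlorophyll is the exact sum of the parts;
in the extreme corner its lower bound is 0.188 rather than the published
0.19 because additivity takes precedence over re-clipping the sum.

Optics per leaf: optical depth τ(λ) = τ₀ + α·Σₚ kₚ(λ)·Cₚ with α = 7 m² g⁻¹
and τ₀ = 0.05; unit-peak Gaussian-sum absorption profiles kₚ with
chlorophyll a bands at 430/662 nm, chlorophyll b at 453/642 nm and a
broad carotenoid blue band (425/450/480 nm); interface reflectance
ρ(λ) = ρ₀ + ρₛ·sᵢ·G(550, 40)(λ) with ρ₀ = 0.04, ρₛ = 0.06 and a
truncated-normal structural factor sᵢ ∈ [−2, 2]; a per-leaf backscatter
fraction bᵢ ~ U(0.35, 0.65) splits the non-absorbed flux:

    A = (1 − ρ)(1 − e^{−τ}),  R = ρ + (1 − ρ)e^{−τ}bᵢ,  T = (1 − ρ)e^{−τ}(1 − bᵢ).

The clean channels partition unity exactly. Gaussian noise
(sd 0.003 per band) is added independently to R and T, and the matching
assay absorbances (from the exact inverse of the quantification
equations) receive sd 0.002 noise. One root seed spawns separate child
streams for pigments, sensor noise and assay noise.

This construction realises the mechanism under study: bᵢ and sᵢ
contaminate the reflectance channel but cancel (bᵢ) or nearly cancel
(sᵢ, outside the green band) in A = 1 − (R + T). Consequently
reflectance variance across leaves peaks in the green band (≈ 547 nm),
the A–R correlation is strongly negative in blue/red and weak at 550 nm,
and absorbance-based calibrations dominate reflectance-based ones. What
the generator does **not** emulate: wavelength-correlated instrument
noise, specular/BRDF effects, water or wall absorption beyond a flat
baseline, anatomical covariates (thickness, SLA/LAI) as separate
drivers, and inter-pigment spectral shifts in vivo. Passing tests
therefore demonstrate the pipeline's correctness and the intended
structural contrast, not field-level accuracy; absolute R² values on
this population sit above what leaves in a greenhouse yield.

## PLS regression

NIPALS with mean-centering only (no variance scaling, smoothing or
derivative preprocessing — standard for contiguous visible spectra where
band variances are physically comparable). Components are extracted
sequentially: w = Xᵀu/uᵀu normalised, t = Xw (for a univariate response
the inner loop converges in one pass; tolerance 1e−10, cap 500),
q = yᵀt/tᵀt, p = Xᵀt/tᵀt, then both blocks are deflated. The model is
also expressed as β = W(PᵀW)⁻¹q with β₀ = ȳ − x̄ᵀβ; the score-space and
β-form predictions agree to 1e−10 and the training scores are mutually
orthogonal. Requests beyond the effective rank truncate with a warning;
a zero-variance response is an error.

Component count is chosen as the smallest-index argmin of the
leave-one-out RMSE curve, capped at min(10, n/3). The LOO predictions
for all nested component counts come from one NIPALS run per held-out
sample (the first a components of a larger fit are exactly the
a-component fit), with each truncated β rebuilt by the same solve a
fresh fit would use — equal to the literal refit-per-sample loop up to
float summation order, and checked against an independent PLS
implementation in the tests.

Outlier screening reports leverage hᵢ = 1/n + Σₐ t²ᵢₐ/(tₐᵀtₐ) against the
3(A+1)/n rule and Hotelling's T² = Σₐ t²ᵢₐ/var(tₐ) against
A(n−1)/(n−A)·F₀.₉₅(A, n−A). Diagnostics are always reported; samples are
dropped (one pass, then refit, no iteration) only when outlier removal
is explicitly enabled, since the emulated procedure's removal policy is
unstated and keeping all samples is the conservative default.

## Phases and metrics

The 150 leaves split uniformly at random (seeded) into 100 calibration
and 50 external-prediction samples. Per sensor and pigment:
calibration metrics come from the final model applied back to the
calibration set, cross-validation metrics from the LOO predictions at
the selected rank, prediction metrics from the untouched 50. R² is the
squared Pearson correlation between measured and predicted (the
1 − SS_res/SS_tot form is logged alongside); slope and offset regress
predicted on measured, matching the scatterplot convention;
RPD = 1/√(1 − R²) with bands ≥3 quality, 2–3 good, 1.5–2 medium, <1.5
poor; bias is the mean signed residual and SEP its bias-corrected
standard deviation, so rmse² = bias² + (n−1)/n·sep² exactly. Bias is
displayed only for the prediction phase; the machine-readable table
keeps full precision while the markdown rendering rounds to two
decimals.

## Problem sizes and determinism

The full study (150 spectra × 301 bands, LOO over 100 samples with up
to 10 components, 8 models) runs in a few seconds on one CPU, so tests
and the reproduction script use the full design rather than a reduced
one. The generator seed and split seed fully determine every number;
the reproduction script derives both from a single command-line seed.

## Known limitations

- Single-response PLS1 only; no PLS2, OPLS or kernel variants, and no
  wavelength selection.
- The generator's parameter values (α, τ₀, ρ₀, ρₛ, noise sd) are chosen
  as one plausible leaf-optics regime; they are not fitted to any real
  spectra and absolute metric levels should not be read as field
  expectations.
- The absorbance definition is the radiometric 1 − (R + T); analyses
  based on log₁₀ optical density require a different pipeline.
- No instrument calibration, resampling from other grids, or binary
  vendor format support.
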