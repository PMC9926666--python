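# Methods

This note documents the models and numerical choices behind `eemferm`: what
is computed, under which assumptions, and what the synthetic data generator
does and does not emulate.

## Spectral model and preprocessing

A 2D fluorescence measurement is a matrix of intensities over an excitation ×
emission wavelength grid (default: excitation 280–700 nm in 10 nm steps;
emission 278–720 nm in 0.45 nm steps, 983 CCD pixels). Two emission-axis
presets exist because instrument descriptions circulate with slightly
different numbers: `caption` (278–720 @ 0.45 nm, the default) and `methods`
(275–725 @ 0.44 nm). A `coarse` preset (4.5 nm) exists for quick exploratory
runs and is not an instrument grid.

Preprocessing is a fixed-order chain of pure, mask-aware steps:

1. **Emission window.** Only pixels with λ_em − λ_ex ∈ [−10, +270] nm are
   kept (inclusive endpoints). Physically: emission below the excitation
   line is scatter artefact; far above it there is no signal.
2. **Smoothing.** Unweighted moving average along emission, default 25
   pixels (≈ 11.25 nm at 0.45 nm/px). At the grid edges the window
   *truncates* to the available pixels rather than padding — no data is
   invented beyond the grid. The mean runs over unmasked pixels only.
3. **Downsampling.** The emission axis is rebuilt at 2 nm by bin-averaging:
   output pixel k covers [c_k − 1 nm, c_k + 1 nm), starting from the first
   native wavelength. Averaging (not decimation) was chosen as the
   variance-reducing reading consistent with the preceding smoothing.
4. **Scatter exclusion** (optional, "fluorescence-only" mode). Pixels with
   λ_em − λ_ex ∈ [−10, +13] nm are discarded; this removes the elastic
   scatter ridge that otherwise dominates spectral variance.
5. **Referencing.** Every spectrum of a well is reduced by the well's first
   spectrum (I − I₀), so models see *changes* since inoculation; negative
   values are meaningful and kept.

Masks only ever grow along the chain; steps 1–4 are local per spectrum,
step 5 is local per well — there is no cross-well information flow.
Unfolding flattens the unmasked pixels excitation-major into feature
vectors; with a shared configuration all wells share one feature index
(4408 features under the defaults with scatter included).

## Regression: SIMPLS and the dual-RMSE criterion

One PLS1 model is fitted per offline parameter (glycerol g/L, CDW g/L, pH)
with de Jong's SIMPLS on mean-centred X and y. Features are *not*
variance-scaled: all pixels share intensity units, and autoscaling would
inflate noise-floor pixels — standard practice for fluorescence data. The
implementation extracts weight vectors maximising covariance with y,
deflating the cross-product vector against an orthonormal basis of the
x-loadings; score orthogonality holds by construction (asserted at 1e-8
relative in tests). Predictions are never clipped to physical bounds: a PLS
model extrapolating outside its calibration span can legitimately report,
say, a negative concentration, and hiding that would mask a model defect.

Model complexity (the latent-variable count) is chosen against *two*
reference interpolations of the offline data: the dense ("full") schedule
(all samples, interval down to 1–1.5 h) and a sparse schedule (6–8 samples
≥ 5 h apart) emulating realistic manual sampling effort. Calibration y
comes from the sparse interpolation; the full interpolation of the *same
spectra* is internal validation. The divergence rule picks the smallest LV
count at which RMSE_Cal,sparse still falls while RMSE_Cal,full rises —
beyond that the model fits artefacts of the sparse linear interpolation, not
biology. When the curves never diverge (common when sparse and dense
trajectories are similar, e.g. strongly limited cultures), the fallback is
the minimum of RMSE_Pred,full,−100 %, the held-out error excluding the
fully supplemented condition, ties broken toward fewer LVs. The −100 %
variant exists because the fully supplemented culture usually lies outside
the calibration span and measures extrapolation rather than transfer.

Relative RMSEs are reported as a percentage of the *measured range*
(max − min) of that parameter's offline values over the experiment's
non-blank conditions within the modeling window. Published tables in this
field are not always internally consistent about the range used, so the
pipeline reports both absolute and relative values and fixes the definition
here.

The sparse schedule itself is selected deterministically (greedy
earliest-first, first and last samples always kept, truncation to at most 8
keeping first/last) — a reproducible stand-in for hand-picked sampling
times.

## PCA diagnostics

PCA (mean-centred, SVD) is a diagnostic, not part of the regression: scores
over cultivation time show which dynamics dominate spectral variance. With
scatter included, PC1 tracks the gross (biomass-driven) signal; excluding
scatter shifts PC1 to fluorescence dynamics. The sign convention (largest
loading element positive) makes runs reproducible.

## OTR monitoring

Headspace oxygen is read through optode quenching, pO₂ = (I₀/I − 1)/K_SV.
During stop-flow measuring phases the cells deplete headspace oxygen and

    OTR = −(dpO₂/dt) · V_g / (V_l · R · T)   [mol O₂ / L liquid / h]

with the slope from an ordinary-least-squares fit over a point window
centred on the phase (default 5 points). Defaults V_l = 0.8 mL,
V_g = 2.6 mL, T = 303.15 K match a 48-round-well plate at the standard
filling volume. This is a plain ideal-gas stop-flow balance; device-specific
corrections (sensor dynamics, diffusion through the seal) are out of scope.
% air saturation converts to bar via 0.2095 bar O₂ at 1 atm.

## The synthetic-data generator

The generator exists so that every pipeline stage is testable without
instrument data. It is this package's own minimal mechanism and is *not* a
fitted model of any particular organism; it reproduces the qualitative
phenomenology of glycerol batch cultures of a GFP-expressing yeast under
secondary substrate limitation:

* **Phase 1** (secondary substrate M and glycerol S present): Monod growth,
  μ = μ_max S/(K_S + S); M and S consumed stoichiometrically
  (Y_X/S = 0.34 g/g, Y_X/M per preset).
* **Phase 2** (M depleted, S left): growth decouples from M — biomass
  accumulates at a slow linear rate while glycerol is consumed for growth
  and maintenance (q_m = 0.02 g/g/h). The linear rate is set per condition
  proportional to the biomass present at the transition
  (`limited_rate_coeff` × X_transition), so a culture with no secondary
  substrate at all shows essentially no activity.
* **Phase 3** (S depleted): growth and uptake stop; pH relaxes first-order
  to its starting value (0.15 /h).

GFP is produced at a rate ∝ X times a saturating derepression term
K_d/(K_d + S) (K_d = 0.5 g/L): negligible at high glycerol, surging as
glycerol runs out. Under limitation the response is substrate-specific:
`stall` (Mg/K presets — production stops in phase 2) or `burst` (PO₄ preset
— the final surge is amplified). After depletion, production decays
exponentially (0.15 /h), giving the asymptotic flattening seen in such
cultures and a late-phase signal correlated with pH recovery. Culture pH
falls linearly with biomass formed (0.128 pH/(g/L), a lumped MES-buffer
acidification) — no rigorous buffer chemistry is attempted. OTR couples to
glycerol uptake through a respiratory yield y_OS = 1.40 mol O₂/mol glycerol
(glycerol molar mass 92.09 g/mol).

μ_max = 0.22 /h and y_OS = 1.40 were calibrated once so the fully
supplemented magnesium-preset culture peaks near the benchmark operating
point of ≈ 34.5 mmol O₂/L/h at ≈ 22.3 h (the simulator reproduces
33.7 mmol/L/h at 22.3 h); they were not revisited afterwards.

Integration is explicit Euler (dt = 0.01 h) with stoichiometric clamping:
within a step, biomass growth is limited by remaining S and M, so the mass
link X − x₀ ≤ Y_X/S (s₀ − S) holds to float rounding, states never go
negative, and with maintenance off the balance closes to < 1e-6.

**Spectra** are sums of unit-height Gaussian fluorophore peaks — GFP
(420/530 nm, amplitude ∝ GFP), NADH (340/450, ∝ metabolically active
biomass X·S/(K_S+S)), flavins (450/530, ∝ X) — plus a biomass-driven
elastic-scatter ridge along λ_em = λ_ex (amplitude saturating in X,
σ = 5 nm), a flat baseline, and Gaussian noise with sd = floor + rel·signal
(defaults 2 a.u. + 1 %), clipped at zero. Peak centres are conventional
literature values chosen to place signal under the standard readout channels
(GFP at ex 420/em 530, scattered light at 600/600); the true spectral shapes
of any real strain/medium differ.

**Plate presets** encode the three limitation experiments: full
supplementation 295.8 mg/L Mg²⁺, 2017.3 mg/L K⁺, 697.9 mg/L PO₄³⁻, with the
published dilution ladders (the media calculator reproduces the printed
concentrations exactly, rounding half-up to 2 decimals below 10 mg/L, else
1 decimal). Each condition gets duplicate wells with independent spectral
noise; offline sampling follows the dense 1.5 h schedule with measurement
noise at stated instrument precisions (glycerol CV 0.2 %, CDW CV 3 %, pH sd
0.02); blanks and per-well pO₂ traces (stop-flow cycles of 6 points over
0.125 h per 0.5 h, flush reset to air saturation — cycle timing is
simulator configuration, not an instrument truth) are included. Everything
is driven by one seed; identical configs reproduce byte-identical plates.

### What passing tests do and do not show

The generator's spectra are *linear-ish* in a handful of latent culture
states with well-behaved noise — friendlier than real spectra, which carry
inner-filter effects, Raman bands, drift, and fluorophores not modelled
here. A sub-10 % held-out prediction error on synthetic plates therefore
validates the *workflow* (preprocessing, alignment, SIMPLS, LV selection,
no data leakage), not the field performance of any instrument. Conversely,
the oracle tests (NIPALS equivalence, brute-force preprocessing loops,
eigendecomposition PCA, closed-form OTR) validate the numerics
unconditionally.

## Numerical choices and degenerate inputs

* Band endpoints (emission window, scatter band) are inclusive on both ends.
* Nearest-pixel channel extraction, no interpolation — single CCD pixels are
  what an instrument reports.
* Offline interpolation is piecewise linear, exact at knots, and refuses to
  extrapolate; spectra outside the sampled range are dropped (with warning)
  from y-bearing datasets but kept for trajectory prediction.
* SIMPLS refuses LV counts beyond the usable rank (reporting the maximum)
  and zero-variance responses; PCA refuses n_pc > min(rows−1, features).
* RMSE of empty vectors, zero reference ranges, ragged spectral grids,
  non-monotonic time axes, inconsistent masks across a well's time series,
  and calibration/prediction condition overlap are all hard errors.
* Down-sampled problem sizes used in the test suite (coarse emission grid,
  hourly cadence, single replicates) are the package's own choice of
  fast-feedback defaults; the acceptance script runs the full-resolution
  default plate.

## Known limitations

* The kinetic scheme is deliberately minimal: no oxygen limitation, no
  fed-batch, no rigorous pH/buffer thermodynamics, no spectral inner-filter
  correction.
* The sparse-schedule selector is a deterministic greedy stand-in for
  hand-picked sampling times; published experiments did not tabulate theirs.
* No cross-validation, wavelength-selection, or nonlinear regression
  variants — the scope is the SIMPLS + dual-RMSE workflow.
* External-data mode expects the package's long-CSV/YAML formats; no vendor
  binary formats are read.
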