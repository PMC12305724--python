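# Methods

This note records the models behind `carotchem`, the defaults that
matter, and the choices made where the design was genuinely open.

## The measurement problem

Purple carrot accumulates five cyanidin glycosides — three acylated
(Cy3XSGG, Cy3XFGG, Cy3XCGG; sinapoyl/feruloyl/coumaroyl) and two
non-acylated (Cy3XG, Cy3XGG) — plus phenolic acids dominated by
chlorogenic (3CQA) and caffeic (CA) acid. Reference quantification is
by UPLC-MS/MS (μg/100 g dry weight); FT-NIR spectra (absorbance vs
wavenumber, 3594–12 489.7 cm⁻¹) offer a cheap non-destructive proxy
once a calibration model links spectra to reference concentrations.
The package builds one PLS1 model per analyte for the ten modeled
responses (five pigments, 3CQA, CA, and the totals Total_ACN,
Total_AcA, Total_PHEN).

## Synthetic cohort generator

No raw study data is deposited, so the generator emulates the cohort
from published summary statistics. It is first-class, tested code —
the conditions it encodes are the conditions every downstream claim is
evaluated under.

**Groups and sizes.** Seven binary phenotype groups. Published
anchors: 165 purple / 296 non-purple of 461 samples, and the group
means of the fully purple (`:1111`, mean Total_ACN 1799.7 μg/100 g dw,
mean acylation 69.5 %) and non-purple (`:0000`, 0.5 μg/100 g dw)
groups, with only purple periderm (`:1000`) carrying the highest
acylation (94.6 %). Individual purple group sizes are not published;
the defaults (60/25/20/25/10/25) sum to 165 with `:1111` large enough
for stable group means. Intermediate group concentration means are
interpolated on the plausible ordering (more pigmented tissues → more
anthocyanin).

**Concentration law.** Per group, total anthocyanin is log-normal,
`ACN = m·exp(σz − σ²/2)` with z standard normal, so the configured
mean is exact and the `:1111` spread (σ = 0.62) reproduces the
published within-group range (~226–4527 μg/100 g dw at n = 60). The
published source gives no distributional form; log-normal is the
standard choice for strictly positive, right-skewed metabolite
concentrations. Components at or below a detection floor (0.02
μg/100 g dw) report as zero, mimicking below-LOD censoring in
non-purple samples.

**Compositional splits.** Total cyanidin mass is split acylated vs
non-acylated by a Beta draw (group-specific mean; concentration ~20–30
so per-sample acylation spans roughly 40–100 %), within-AcA by a
Dirichlet with mean shares (0.502, 0.473, 0.025) taken from the
`:1111` component means, and within-NAA (Cy3XG vs Cy3XGG share) by a
second Beta with mean 0.86. The published compositional *correlations*
— r(%Cy3XG, acylation) = −0.9, r(%Cy3XFGG, %Cy3XSGG) = −0.8 — are
emergent properties of the split variances, not direct parameters, so
the two concentration parameters (NAA-split κ = 1.6, AcA-Dirichlet
κ = 2.5) were fixed by a single seeded grid search
(`scripts/tune_generator.py`) and frozen. The resulting splits are
deliberately diffuse: individual samples range from feruloyl- to
sinapoyl-dominated and some carry no detectable Cy3XG, matching the
published per-sample extremes (%Cy3XFGG 2.3–77.8 %).

**Phenolic acids.** `PHEN = m_P·exp(σ_P z_P − σ_P²/2)` with
`z_P = ρz + √(1−ρ²)z'` sharing the latent factor z that drives ACN;
ρ = 0.35 (same grid search) yields cohort correlations of ~0.46 (all
461) and ~0.49 (purple only). The `:0000` PHEN mean (165 μg/100 g dw,
unpublished) sits between the purple extremes — non-purple carrots
still accumulate chlorogenic acid. PHEN is split 3CQA/CA/other by a
tight Dirichlet around (0.87, 0.06, 0.07) from the published `:1101`
component means.

**Spectra.** Beer–Lambert forward model on a 3594–12 489.7 cm⁻¹ grid
at 7.7 cm⁻¹ spacing (1156 points; the instrument's optical resolution
is 16 cm⁻¹, digitisation spacing is a free configurable choice). Each
analyte contributes 2–4 Gaussian bands placed inside the wavenumber
windows its calibration model retains; a shared "matrix" component
(broad water/carbohydrate bands, unit concentration for every sample)
dominates raw absorbance ~10:1 over the analyte signal. Caffeic acid,
present at ~20× lower concentration than chlorogenic acid, is assigned
a proportionally larger per-unit absorptivity so its signature stays
above the noise floor — distinct absorptivities per analyte are the
physical norm. Each replicate scan applies
`A = slope·(mixture + baseline) + noise` with slope ~ 1 ± 0.05,
baseline offset 0.02 ± 0.01 plus a ≤10⁻⁶ cm⁻¹ linear tilt, white noise
SD 10⁻³ absorbance, and a 1 % replicate-to-replicate jitter. Negative
points are clipped to zero and counted. With scatter and noise off the
model is exactly linear in concentrations (machine precision), which
the suite exploits as an oracle.

**Extracts.** Per-pigment extraction efficiencies (means 98 % Cy3XGG,
82.3 % Cy3XFGG, 79 % Cy3XSGG, 78 % Cy3XCGG, 85 % Cy3XG; SD 4) map
puree to extract concentrations; A520 responds linearly with the
largest coefficient on Cy3XSGG, A420 adds a browning term, A700 is
small turbidity. Coefficients are scaled so the default `:1111` cohort
reaches color densities of order 40–80.

**What the generator does *not* emulate.** Real NIR spectra carry
correlated (pink) noise, water-band saturation, temperature-dependent
band shifts, and nonlinear detector response; real metabolite tables
carry genotype structure (families, repeated accessions) beyond the
seven phenotype groups. Passing tests therefore demonstrate that the
pipeline is correct and attains the published accuracy regime *under
Beer–Lambert conditions with the published noise magnitudes* — they do
not certify instrument-grade performance on field samples.

## Preprocessing

Per-analyte chains follow the published treatment: SNV for the
anthocyanin models, first derivative + vector normalisation for
Cy3XFGG, first derivative + MSC for Total_PHEN, first derivative + SNV
for 3CQA and CA, each followed by that analyte's wavenumber windows.
Operator order (derivative → scatter correction → window last),
Savitzky–Golay parameters (window 17, polyorder 2, same-length output
with polynomial edge handling), and closed window intervals are fixed
here because the source names operators and windows but not order or
parameters. SNV uses the sample (n−1) standard deviation. MSC stores
the calibration-set mean as its reference; prediction-time transforms
always replay stored state (MSC reference, window mask) and never
statistics of the prediction set.

## PLS1 and rank selection

NIPALS with deflation; for a single response the per-component
iteration converges in one sweep (tolerance 10⁻¹², cap 500 iterations
kept for the general case). A component carrying no remaining
covariance stops extraction early with the achieved rank recorded;
rank 0 is a contract error. Default max rank 10 (configurable).
Replicate scans enter as separate rows but are fold-grouped by sample
id in all cross-validation — the statistically defensible reading of
triplicate scanning, preventing replicate leakage from inflating CV
accuracy. Fold assignment is seeded and concentration-stratified
(samples sorted by mean response, dealt into folds within shuffled
blocks of k) to stabilise small-n CV.

## Validation conventions

R² is 1 − SSres/SStot on validation pairs (not squared Pearson). RMSE
uses the n denominator; the SD in RPD uses n−1. Stated explicitly
because the mismatch is exactly why RPD ≠ 1/√(1−R²) at small n — the
suite asserts the matched-denominator identity, and the package
documents its own conventions rather than guessing those of
proprietary calibration software (whose published R²/RPD pairs are not
mutually consistent under any single convention). Zero RMSE reports
RPD as an infinity flag, not an exception. Bias is mean(ŷ − y),
positive = overestimation.

## Noiseless-limit checks

With SNV (or MSC/vector normalisation) in the chain, the transform
destroys the per-spectrum scale, so even noiseless data cannot be fit
to machine precision through it. The noiseless-limit checks (CV
R² → 1 within 10⁻⁶ for all ten analytes) therefore run with the
scatter-correction steps dropped (derivative and windows kept), which
is the scientifically meaningful limit: scatter corrections exist to
remove scatter, and with none simulated they only discard information.
The default-noise pipeline always runs the full chains.

## Diversity and composition conventions

Shannon–Wiener H uses natural logarithms (the base is not stated in
the source); E = H/ln S (Pielou), defined as 0 for a single category.
Percentage composition and compositional correlations exclude samples
whose total anthocyanin is at or below the detection floor, where
shares are meaningless. Correlation p-values are reported unadjusted,
matching the source presentation; hue is flagged undefined (NaN) when
A420 = A700. Extraction efficiencies above 100 % are kept but warned
about (measurement noise), never clipped.

## Problem sizes

Defaults mirror the study scale: 461-sample cohorts for composition
statistics, 160 purple samples × 3 replicate scans for calibration
runs, 50/100 calibration/validation splits for external validation.
The test suite exercises the same code paths on proportionally reduced
cohorts (~20–60 samples) chosen to keep the full suite fast while
leaving every statistical check well-powered.

## Known limitations

- One model per analyte (PLS1); no multi-response PLS2, PLS-DA, or
  automated wavelength search (the published windows are fixed
  defaults).
- The JCAMP-DX reader covers AFFN `XYDATA=(X++(Y..Y))` and
  `XYPOINTS=(XY..XY)`; compressed (DIFDUP) encodings and multi-block
  files are out of scope, as are proprietary instrument binaries.
- Tukey HSD group lettering is not reproduced; group summaries stand
  in.
- The anthocyanin unit scale (μg/100 g dw) is taken at face value from
  the source even though it sits oddly against fresh-weight figures
  cited elsewhere; the package does not attempt to reconcile units.
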