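# Methods

This note documents the models implemented in `alqc`, the assumptions behind
them, the defaults and why they were chosen, and what the synthetic data can
and cannot show about real measurements.

## Spectral model and the synthetic study

A tablet's pseudo-absorbance spectrum is modelled as a weighted sum of
pure-component signatures plus scatter and detector noise:

    x(λ) = g · Σ_c w̃_c · s_c(λ) + o + ε(λ)

where each component signature `s_c` is a sum of 2–4 Gaussian bands on
900–1700 nm, `g = exp(N(0, σ_mult))` and `o ~ N(0, σ_add)` are per-tablet
multiplicative/additive scatter, and `ε` is additive detector noise with
SD 1e-3 inside the 1085–1601 nm core window and 5e-3 outside it (the edge
regions of this detector class are noisier, which motivates the truncation
step). The weights `w̃_c` are the formulation's mass fractions perturbed by
independent per-component lognormal factors, first per batch
(σ_batch = 0.005) and then per tablet (σ_tablet = 0.01): batch-mean
composition is controlled more tightly than single-tablet content
uniformity, so the batch SD sits below the tablet SD.

The default study reproduces a realistic market survey: seven products
(six licit brands, one falsified illicit-channel product), 27 batches, ten
tablets per batch, 270 spectra. All licit products share the API fractions
of a 20/120 mg tablet (artemether 1/24, lumefantrine 1/4 of tablet mass);
the falsified product contains no API at all, its mass being starch plus a
pigment imitating lumefantrine's yellow colour.

Two design principles shape the component library:

* a Savitzky–Golay second derivative attenuates a Gaussian band roughly as
  amplitude/width², so broad filler bands (cellulose, lactose, starch)
  nearly vanish while narrow bands of minor crystalline components
  (disintegrant, binder, glidant, lubricant) dominate. Brand identity is
  therefore carried by distinct *marker profiles* over those minor
  components, the way real NIR brand discrimination is usually driven by
  excipient differences rather than the shared API;
* band amplitudes run roughly inverse to typical mass fractions, so each
  component perturbs the preprocessed spectrum by a comparable amount per
  unit relative weight change. No single component then dominates the
  within-brand covariance, which keeps the DD-SIMCA distance distributions
  close to their chi-square model.

Under the defaults, the smallest between-brand mean distance in
preprocessed space (the deliberately similar AL Ipca / Komefan and
AL Ipca / Artefan-dispersible pairs) is ≈6× the pooled within-brand SD; the
two near-twin brands differ only in binder fraction (0.01 vs 0.06), which is
invisible in PC1–PC2 but resolved by the class models.

**What the generator does not model:** Kubelka–Munk radiative transfer,
particle-size and compaction effects, moisture bands, wavelength-axis drift,
blister interference, or instrument-to-instrument variation. Passing tests
therefore demonstrate the correctness and internal consistency of the
chemometric pipeline under a controlled spectral mixture model — not the
field performance of any instrument.

## Preprocessing

The chain is SG second derivative → MSC → truncation to 1085–1601 nm.

* **SG window 11 points** (~39 nm on the default 228-point grid): standard
  for low-resolution NIR; the polynomial degree and derivative order are
  both 2. The filter output keeps the valid interior only, dropping
  (window−1)/2 points per edge, so no padded boundary values reach MSC. The
  derivative is per grid index; all downstream statistics are invariant to
  this global scale.
* **MSC** regresses each spectrum on a reference (`x ≈ a + b·ref`, OLS) and
  corrects to `(x−a)/b`. The reference is the mean of the *fitted* set —
  global for exploratory PCA, class-mean for DD-SIMCA training — and is
  stored in a `PreprocessState`, so new samples are always corrected against
  the training reference; re-fitting on test data is a separate explicit
  call. A slope |b| < 1e-12 raises an error naming the sample.
* **Truncation last** (SG and MSC run on the full recorded range) so SG edge
  artefacts fall outside the analysis window; a `truncate_first` flag
  provides the alternative order.

## PCA

Deterministic SVD on mean-centered data (derivative+MSC spectra are already
on a common scale, so no autoscaling in the exploratory step), with the sign
convention that each loading's largest-magnitude element is positive;
eigenvalues use the (I−1) denominator. The per-plane 95% confidence region
is the Hotelling T² ellipse `(t−t̄)ᵀS⁻¹(t−t̄) ≤ 2(I−1)/(I−2)·F⁻¹(γ; 2, I−2)`
— a per-score-plane choice, documented as such.

## DD-SIMCA

Training spectra of the target class are autoscaled (mean/SD per variable;
zero-variance variables are dropped with a warning and recorded), then
decomposed by PCA with A components. For each sample `h = Σ t²ₐ/λₐ` and
`v = ‖residual‖²`; both are modelled as scaled chi-squares whose scales
(h₀, v₀: training means) and degrees of freedom (N_h, N_v: classic moment
estimator `round(2·mean²/var)` clamped to [1, 250]) come from the training
distances. The combined statistic `c = N_h·h/h₀ + N_v·v/v₀` is compared to
`χ²₁₋α(N_h+N_v)`; the acceptance plot uses `ln(1+h/h₀)` vs `ln(1+v/v₀)`.

Splitting is by batch, never by tablet: models are built only for products
with ≥5 collected batches, trained on the first three, tested on the rest;
every other product (including the falsified one) forms the specificity
sets. No training-set outlier purge is applied.

**(A, α) optimisation.** Acceptance regions are nested in α, so sensitivity
is maximal at the smallest α of the grid (default 1e-6…1e-2). Stage 1 picks
the smallest A reaching 100% test sensitivity at that most lenient α;
stage 2, at that A, picks the most stringent α retaining 100% sensitivity
with maximal specificity. If no grid point reaches full sensitivity the
best-sensitivity model is returned with a warning flag.

**Known limitation.** With ~30 training spectra and ~146 variables, the
in-sample distances underestimate fresh-sample distances by ~30–40%
(per-variable SDs, the PC subspace and v₀ are all fitted to the same 30
samples), so fresh same-brand tablets carry a residual ≈0.3% rejection
probability even at α = 1e-6. On the default study this occasionally costs
a single held-out tablet (sensitivity 95–96.7% instead of 100% on roughly a
quarter of random seeds). Robust DD-SIMCA dof estimators mitigate but do
not remove this; the classic estimator is the one implemented.

Models serialize to a single JSON file embedding the preprocessing state;
save→load reproduces distances bit-identically.

## Accuracy-profile validation

Calibration uses one concentration level (100%: 0.1 mg/mL artemether,
0.012 mg/mL lumefantrine) in duplicate per day, giving a through-origin
per-day response factor `b_j = mean(area)/c₁₀₀` (a single level cannot
estimate an intercept; the reported "intercept" belongs to the linearity
regression of back-calculated on introduced concentrations, pooled over the
design). Back-calculated validation concentrations (3 days × 3 replicates ×
levels 80/100/120%) feed, per level, the balanced one-way random ANOVA:

    MS_B = n·Σ(x̄_j−x̄)²/(p−1),  MS_W = ΣΣ(x_jk−x̄_j)²/(p(n−1))
    σ_W² = MS_W,  σ_B² = max(0, (MS_B−MS_W)/n)   (negative estimates clamp)
    R = σ_B²/σ_W²,  B² = (R+1)/(nR+1)
    ν = (R+1)² / [ (R+1/n)²/(p−1) + (1−1/n)/(pn) ]     (Satterthwaite)
    k = t_{ν,(1+β)/2} · √(1 + 1/(p·n·B²))
    tolerance limits (%) = bias% ± k·100·σ_IP/μ_T,  σ_IP² = σ_W²+σ_B²

with β = 0.90 and all RSDs and biases expressed relative to the introduced
concentration μ_T (not the observed mean). The method is valid iff every
level's interval lies inside ±10%; LLOQ/ULOQ are then the dosing-range
endpoints, and a failing terminal level is interpolated linearly to the
crossing of its tolerance bound with the limit. Monte-Carlo checks in the
test suite confirm that ≈90% of future observations fall inside the
intervals and that bias and variance components are recovered.

The validation generator applies the shared day effect γ_j to calibration
and validation areas alike — daily calibration is precisely how laboratories
cancel day-to-day response drift — so the residual between-day component of
back-calculated results stems from calibration replicate error. Generator
defaults (bias +2% at the 80% level, σ_day 2%, σ_rep 1.5%) produce RSDs and
interval widths of the magnitude a well-behaved assay prints; with p = n = 3
the interval half-width is itself an estimate with few degrees of freedom,
so occasional seeds produce intervals beyond ±10% and an honestly invalid
verdict.

## Tablet assay and API detection

Powdered-tablet stock targets 1.2 mg/mL lumefantrine (0.2 mg/mL
artemether); a 1:2 dilution yields the artemether working solution and a
1:100 dilution the lumefantrine one. Content (%) is the back-calculated
injected concentration × dilution factor, referenced to the nominal stock
concentration. `detect_api` reports "not_detected" below 1% of label claim
(configurable; the boundary is closed — exactly 1% counts as present).
Contents between 94% and 106% are treated as conforming.

## Chromatographic figures of merit

`k = (t_R − t₀)/t₀`; tailing factor `As = w₅/(2f₅)` at 5% peak height
(pharmacopoeial definition); resolution `Rs = 1.18(t_R2 − t_R1)/(w_h1 +
w_h2)` from half-height widths. Peak integration from raw chromatograms is
out of scope; the inputs are peak descriptors.

## Greenness

The Eco-scale engine scores 100 minus penalty points: per reagent, an
amount band (<10 mL → 1; 10–100 mL → 2, both boundaries in the middle band;
>100 mL → 3) multiplied by a hazard sub-penalty (pictogram count × signal
word weight, warning 1 / danger 2; no pictograms → no penalty); instrument
penalties for energy (≤0.1 kWh/sample → 0; ≤1.5 → 1; >1.5 → 2), vapor
emission (3) and waste volume (0 → 0; <1 mL → 1; 1–10 → 3; >10 → 5). The
extra no-treatment waste penalty (+3, degradation +1) exists behind an
opt-in flag, off by default, matching the plain amount-banded reading. All
bands live in module-level tables a user can edit. NEMI flags: PBT and
Hazardous green iff no reagent is listed; Corrosive green iff 2 ≤ pH ≤ 12;
Waste green iff <50 g/sample. A small bundled reagent table covers the
common solvents (water, ethanol, acetic acid, acetonitrile, methanol,
hexanesulfonate); membership in regulatory lists is user-supplied data, not
a database query.

The bundled `green_hplc_method()` records the ethanol/acetic-acid assay the
package's validation example uses (ethanol and water in the 10–100 mL band,
acetic acid <10 mL, ≤0.1 kWh/sample, hermetic, 1–10 mL waste, mobile phase
pH 3.35, <50 g waste/sample), scoring 94/100 with an all-green NEMI label.

## Numerical and interface choices

* Spectra are generated and processed as pseudo-absorbance; the convention
  does not affect any implemented statistic.
* Wavelength grid: 228 evenly spaced points on [900, 1700] nm
  (instrument-typical pixel count), configurable.
* All generators take an explicit integer seed and are bit-reproducible;
  the CLI writes a `run_info.json` sidecar with the seed and the SHA-256 of
  the resolved config next to every output set.
* Problem sizes in the test suite (e.g. 2000-sample coverage checks, 10⁴
  Monte-Carlo tolerance-interval replicates) were chosen so the whole suite
  runs in seconds while keeping Monte-Carlo standard errors well inside the
  asserted tolerances.
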