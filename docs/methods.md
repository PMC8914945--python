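# Methods

This note documents the models, algorithms and numerical choices behind
`lsratio`, and the reasoning at the points where the design was genuinely
open.

## 1. The measurement model

A measurement is an absorbance spectrum A(ν) on a uniform wavenumber grid
(raw generation grid 600–4000 cm⁻¹, step 2 cm⁻¹).  The generator's forward
model is

```
A(ν) = g_s · [ c_DPPC · r_DPPC(ν − δ) + c_SM · r_SM(ν − δ) ]      (analyte signal)
     + a_v · v(ν) + a_w · w(ν)                                     (vapor artifacts)
     + β₀ + β₁·(ν − ν̄) + d(ν) + t(ν)                              (background)
     + ε(ν),   ε ~ N(0, σ²) iid                                    (detector noise)
```

with r_DPPC, r_SM the unit-concentration component spectra rendered as sums
of Lorentzian bands at the tabulated DPPC and SM band positions (carbonyl
1734 cm⁻¹ unique to DPPC, amide I 1646 cm⁻¹ unique to SM, overlapping C–H,
phosphate and choline bands elsewhere).  Beer–Lambert linearity in the
concentrations is exact by construction.

Term by term:

- **g_s** — session-level detector gain, N(1, 0.001²).  A fresh background
  is recorded before each set of scans, so almost all gain drift cancels;
  only a small residual session effect remains.
- **δ** — per-measurement band-position jitter, N(0, 0.3²) cm⁻¹,
  representing temperature/composition shifts of liquid-phase band centers
  (samples are heated and vortexed immediately before dispensing and
  equilibrate on the crystal).  Implemented by re-evaluating the analytic
  line shapes on a shifted grid, so it is exact rather than interpolated.
- **v(ν)** — negative dichloromethane-vapor difference bands near 3000,
  1600, 1420 and 900 cm⁻¹ (vapor imbalance between background and sample
  scans), amplitude uniform on [0, 2×10⁻⁴] A.U. per measurement.
- **w(ν)** — water-vapor interference: ~60 narrow (4 cm⁻¹ FWHM) lines of
  fixed position and sign in 1400–1900 cm⁻¹ (fixed because real water lines
  do not move), amplitude up to 3×10⁻⁴ A.U. on a random ~30 % subset of
  replicates.  Each dispensed sample always retains at least one
  interference-free replicate.
- **β₀, β₁** — per-measurement baseline offset (sd 5×10⁻⁴ A.U.) and tilt
  (sd 1×10⁻⁷ A.U./cm⁻¹).
- **d(ν), t(ν)** — smooth ATR background variation: a cubic-spline drift
  with 800 cm⁻¹ knot spacing (knot sd 6×10⁻³ A.U.) and a finer 300 cm⁻¹
  texture (knot sd 8×10⁻⁴ A.U.), both modulated by a low-wavenumber
  envelope (((ν_max − ν)/range)³ for both).  ATR backgrounds are larger and
  less reproducible at longer wavelengths because those wavelengths travel
  a longer optical path in the medium; the envelope also keeps the
  2450–2640 cm⁻¹ noise-estimation window essentially signal-free, which the
  processing chain relies on.
- **σ** — instrument noise floor, 4×10⁻⁵ A.U.

The background terms were calibrated jointly so that the end-to-end
pipeline reproduces the qualitative performance regime the method is known
for: second-derivative models outperform original-spectra models (the
smooth drift confounds absorbance-domain models but carries almost no
second derivative), while bootstrap prediction intervals achieve near-
nominal coverage (per-measurement error sources dominate the residual
session-level effects, so resampling calibration data can represent them).

### Campaign structure

The default campaign is 10 sessions with measurement counts
(31, 31, 31, 31, 31, 21, 21, 21, 21, 20) — 259 spectra in total.  Each
session dispenses a sequence of samples at L/S ratios cycled from
{1.0, 1.7, 2.0, 2.1, 2.2, 2.3, 2.4, 2.7, 3.4} on a 1 mM SM basis and
records 6–18 successive scans per sample (the last run of a session is
truncated to fit the session total).  Assigning the five size-31 sessions
to calibration produces the 155/104 calibration/test split used throughout.
Per-session measurement counts and replicate structure are not observable
design constants; they are documented fabrications consistent with the
totals above.

## 2. Spectral processing

Order: truncate → baseline offset → zap → (optional) second derivative.

- **Truncation** to the closed interval [830, 3500] cm⁻¹ (1336 points on
  the 2 cm⁻¹ grid).
- **Baseline offset**: subtract the absorbance at the grid point nearest
  2500 cm⁻¹.  This is a literal single-point correction; the second
  derivative is insensitive to the choice, and original-spectra models see
  exactly what a minimal point-of-care processing chain would produce.
- **Zapping**: the CO₂ (2150–2430 cm⁻¹) and strongest-solvent
  (1190–1310 cm⁻¹) regions are replaced by N(0, σ²) draws at the noise
  floor so they carry no information.  Zapping precedes the derivative, so
  the filter runs across the noise-filled regions and produces edge
  artifacts at the region boundaries; this mirrors the processing order of
  instrument software followed by downstream analysis and is accepted.
- **Noise estimation**: sample standard deviation in 2450–2640 cm⁻¹ after
  subtracting a best-fit straight line, so slow baseline does not inflate
  the estimate.
- **Second derivative**: single-pass Savitzky–Golay filter, 15-point
  window, polynomial order 3, derivative 2, in A.U./(cm⁻¹)².  Edge points
  come from the polynomial fitted to the one-sided edge window, preserving
  the point count.  A gap-segment derivative would be an alternative; the
  single-pass filter is the simplest standard choice and reproduces
  polynomials up to degree 3 exactly, which the tests exploit.

## 3. Calibration models

Both models operate on mean-centered spectra and concentrations; spectra
are **not** variance-scaled (channels share units, and scaling would
amplify noise-only channels such as the zapped regions).

- **PCR**: SVD of centered X; ordinary least squares of centered Y on the
  first k score vectors.  Because scores are orthogonal, per-component
  regression coefficients are independent of k, so one fit at k_max yields
  every truncated model — the basis of the fast cross-validated factor
  scan.  Components with singular values below 10⁻¹² of the largest are
  treated as null and zero-padded.
- **PLSR**: NIPALS PLS2.  Per factor, the inner power iteration converges
  to the dominant direction of XᵀY (tolerance 10⁻¹² on the weight vector,
  max 500 iterations); scores t = Xw, loadings p = Xᵀt/tᵀt, q = Yᵀt/tᵀt;
  X and Y are deflated by t.  Coefficients B = W(PᵀW)⁻¹Qᵀ, assembled for
  any truncated factor count.  A constant response column (SM at 1 mM)
  contributes a zero column to XᵀY and is handled without special-casing:
  its coefficients are exactly zero and its predictions equal the training
  mean, with joint modelling of the varying column unaffected.  With a
  single effective response the inner loop converges in one step, which is
  why bootstrap refits are cheap.
- A PLS1-per-analyte fit is available by passing a single-column Y; the
  default is one joint PLS2 model producing a concentration per analyte.

Model performance is summarized by R² = 1 − Σ(y−ŷ)²/Σ(y−ȳ)² and MSE;
R² is undefined (and reported as null) for a constant truth such as SM.

## 4. Validation and factor selection

- **Split**: by whole sessions, never by spectra — replicates within a
  session share instrument state, and splitting within sessions leaks that
  state into the test set.  Random halves assign ceil(n/2) sessions to
  calibration; an explicit assignment pins the documented 155/104 split.
- **Cross-validation**: K-fold (default k = 10, one repeat) over
  calibration spectra.  Fold membership is drawn over spectra rather than
  sessions: the CV's role here is factor-count selection, and the final
  test evaluation is session-grouped.  Training metrics are averaged over
  folds; held-out metrics are pooled over all held-out predictions
  (PRESS form: R²_CV = 1 − PRESS/SS_tot), which is the standard
  chemometric Q² and remains defined for leave-one-out folds.
- **Selection rules**: `min_cv_mse` (argmin), `parsimony` (smallest count
  within 10 % of the minimum CV MSE — an explicit codification of
  preferring fewer factors to avoid modelling noise), and `fixed:n`.  The
  default experiment pins the four variants at 5 (PCR/original) and 3
  factors (the others), the counts a CV inspection of this design
  supports.

## 5. Bootstrap prediction intervals

For a test spectrum, the 95 % prediction interval is the empirical
(2.5, 97.5) percentile band of n_boot (default 500–1000) bootstrap draws:

1. Resample the calibration set with replacement — by whole sessions when
   session labels are available (the default in the experiment driver).
   Sessions are the independent sampling unit; row resampling understates
   between-session uncertainty and measurably under-covers.
2. Refit the model on the resample and predict the test spectra.
3. Add a residual drawn from the refit's out-of-bag calibration residuals.
   In-bag residuals are shrunken by the fit; out-of-bag errors are honest
   prediction errors.  (If a resample leaves almost nothing out, the full
   calibration set is used.)

The point estimate always comes from the full-calibration fit.  Percentile
(not BCa) intervals are used: simple, reproducible, and adequate at these
resample counts.  For the L/S ratio, each draw's ratio is formed from that
draw's DPPC and SM values; draws with SM ≤ 0.05 mM are rejected and
counted, and a rejection rate above 5 % flags the interval's metadata
(with SM near 1 mM this is never triggered in practice).  A degenerate
(zero-width) percentile band — possible on noiseless data — is widened
symmetrically by one part in 10¹² to preserve the strict lower < upper
contract.

The interval-aware diagnostic call compares the whole ratio interval with
the 2.2 cut-off: `nRDS_likely` if the interval lies below, `nRDS_unlikely`
if at or above, `indeterminate` if it straddles.  The three-way call is an
extension of the scalar cut-off comparison (also provided) so that the
uncertainty the interval expresses reaches the clinical decision.

## 6. Problem sizes and determinism

The test suite and the acceptance script run the full 259-spectrum design.
Coverage is assessed over five seeded replicate campaigns (520 pooled test
predictions, 500 bootstrap refits each); the ordering comparison between
second-derivative and original-spectra models uses medians over ten seeded
campaigns.  Every stochastic stage (generation, zap fill, CV folds,
bootstrap) takes an explicit seed, and identical configurations produce
byte-identical outputs, including the experiment summary JSON.

## 7. What the generator does and does not capture

It captures: Beer–Lambert mixing with realistic band overlap, a correct
noise floor, session structure with replicate runs, water-vapor and
solvent-vapor interference, smooth background variation with the
long-wavelength bias characteristic of ATR, and band-position variability.

It does not capture: ATR penetration-depth dispersion (the wavelength-
dependent effective path length), film-drying or precipitation phenomena,
detector nonlinearity, fringing, or temperature-dependent band-shape
changes beyond a rigid position shift.  Real dichloromethane also absorbs
outside the single zapped window.  Passing results therefore demonstrate
that the pipeline is implemented correctly and behaves as designed under
the assumed error structure — not that a real instrument will reach the
same accuracy.  On real data the second-derivative models' advantage and
the interval coverage should be re-verified, since both depend on the
balance between smooth-background and sharp-feature error sources.

## 8. Known limitations

- Absolute band intensities are not published for these analytes in this
  solvent; the generator's 4×10⁻³ A.U./mM strongest-band height (SNR ≈
  100:1 at 1 mM) and the 0.3–0.9 relative scaling of other bands are
  plausible but invented, so absolute MSEs are not transferable to an
  instrument.
- With SM fixed at 1 mM in the default design, the models cannot be
  validated for SM quantification; ratio error equals DPPC error by
  construction.
- Five calibration sessions estimate session-level variability coarsely;
  prediction intervals inherit that coarseness regardless of n_boot.
- The JCAMP-DX reader supports AFFN encoding only (no DIFDUP compression)
  and the XYDATA / XYPOINTS forms.
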