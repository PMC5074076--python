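# Methods

## The model

`renalreab` predicts renal excretion clearance (CL_R) for drugs whose renal
handling is dominated by glomerular filtration and passive tubular
reabsorption.  The starting point is the standard decomposition

    CL_R = CL_filt + CL_sec · (1 − F_reab),    CL_filt = GFR · f_u,p

with the active-secretion term CL_sec fixed at zero: the model is only
applicable to drugs that pass a net-secretion screen (clearance ratio
CL_R/CL_filt ≤ 1.5), and `renalreab.model.is_net_secreted` implements that
screen with a strict inequality, so a drug sitting exactly on the cut-off is
retained.

The nephron tubule is represented as four well-mixed compartments in
anatomical order — proximal tubule (PT), loop of Henle (LoH), distal tubule
(DT), collecting duct (CD) — each with a tubular surface area TSA_i (m²)
and a midpoint tubular flow rate TFR_i (mL/min).  Passive reabsorption in a
region is scaled from Caco-2 apparent permeability by in vitro–in vivo
extrapolation:

    CL_int,i = P_app · TSA_i                      (IVIVE scaling)
    F'_i     = CL_int,i / (TFR_i + CL_int,i)      (regional equilibration)
    F'       = 1 − Π_i (1 − F'_i)                 (regions in series)

F' is the fraction of the plasma–urine unbound-concentration equilibrium
reached by the end of the tubule.  Because urine keeps flowing, complete
equilibrium (F' = 1) still exports drug at UF · f_u,p mL/min, where UF is
the urine flow; F' therefore maps onto the fraction reabsorbed as

    F_reab = F' · (CL_filt − UF · f_u,p) / CL_filt
    CL_R   = CL_filt − F' · (CL_filt − UF · f_u,p)

giving hard bounds UF · f_u,p ≤ CL_R ≤ GFR · f_u,p that the test suite
asserts for every drug and variant.  The model is static: regional
equilibration fractions compose multiplicatively and no back-flux,
urine-concentrating mechanism, renal metabolism or plasma kinetics is
represented.

### Units

P_app is carried in 10⁻⁶ cm/s and TSA in m², so the intrinsic clearance in
mL/min is `papp · tsa · 0.6` (10⁻⁶ cm/s × 10⁴ cm²/m² × 60 s/min).  Getting
this factor right is what the caffeine/antipyrine fold-error anchors in
`tests/test_acceptance.py` pin down.

## System parameters

Defaults (module `renalreab.physiology`), for a healthy adult:

| region | TSA (m²) | TFR (mL/min) | flow in → out (mL/min) |
|--------|----------|--------------|------------------------|
| PT     | 6.1      | 81.6         | 120 → 43.2             |
| LoH    | 0.16     | 33.6         | 43.2 → 24.0            |
| DT     | 0.21     | 17.8         | 24.0 → 11.6            |
| CD     | 0.045    | 6.3          | 11.6 → 1.0             |

GFR = 120 mL/min, urine flow UF = 1 mL/min.  TFR_i is defined as the mean
of the boundary flows (asserted to 1e-9 at construction); flow is strictly
decreasing along the tubule and terminates at the urine flow.

The LoH/DT/CD areas carry a **microvilli correction**: geometric
open-cylinder areas are divided by 7.5 because those segments largely lack
the dense microvilli of the PT brush border (and of the Caco-2 monolayers
the permeability was measured in), so their effective absorptive area per
unit of geometric area is far smaller.  `apply_microvilli_correction` is an
exact involution pair (disable multiplies LoH/DT/CD by the factor, enable
divides; PT is never touched), and the `no_microvilli` model variant runs on
the uncorrected areas.

The packaged table values are authoritative; a secondary, config-driven
geometric path recomputes areas from tubule dimensions when the user can
supply them (they are not bundled):

* `cylinder_tsa(length, diameter, count)` for straight segments;
* `imcd_surface_area` for the inner-medulla collecting duct (IMCD), whose
  ducts repeatedly fuse on the way to the papilla.  The total IMCD
  circumference at distance x from the papilla apex is modelled as

      C(x) = d₀ · NCD₀ · π · exp( x · (F/n) · ln( 2 / (d₀/dₙ)^(1/F) ) )

  with d₀, dₙ the duct diameters at the apex and the outer–inner medulla
  boundary, NCD₀ the duct count at the apex, F the number of fusion events
  and n the inner-medulla width (11 mm).  The printed source formula is
  typeset ambiguously; the grouping above is the one consistent with the
  geometry (each fusion doubles the count walking away from the apex while
  the diameter shrinks by the per-event ratio (d₀/dₙ)^(1/F); at x = n the
  expression collapses to NCD₀·2^F ducts of diameter dₙ).  The surface area
  is the integral of C over [0, n], evaluated with adaptive quadrature
  (absolute tolerance 1e-10 mm²; the integrand is a smooth exponential) and
  cross-checked in tests against a 10⁵-point trapezoid oracle to 0.1%.

Sensitivity transforms (`with_urine_flow`, `with_gfr`, `with_cd_tfr`,
`with_microvilli_factor`) adjust the coupled quantities consistently: a new
urine flow also moves the CD outflow and hence the CD midpoint flow, which
is why predicted CL_R is monotone increasing in urine flow (both the
equilibrium floor and the CD flow rise).

## Observed quantities

From pooled clinical data, with GFR fixed at 120 mL/min:

    F_reab(obs) = 1 − CL_R(obs)/CL_filt
    F'(obs)     = F_reab(obs) · CL_filt / (CL_filt − UF · f_u,p)

Observed F_reab can be negative (e.g. atenolol, −0.25): an artefact of the
1.5 clearance-ratio inclusion cut combined with the fixed GFR.  Negative
values are **retained in all numerical analyses** (fits, stratification —
they land in the "low" category) and clamped to zero only for presentation.
Observed F' can likewise slightly exceed 1 (isoxicam, 1.004), which matters
for the calibration fit below.

## Hill regression and permeability calibration

The P_app–F' relationship is sigmoidal in log P_app and modelled by the
Hill equation F' = P^a / (b^a + P^a), where b is the permeability at
half-equilibration.  `HillCurve` fits it by bounded trust-region least
squares (a ∈ (0, 20], b ∈ (0, 1000], start a = 2, b = median(P_app),
unweighted — no weighting scheme is justified by the data).  Confidence
intervals are asymptotic: s²(JᵀJ)⁻¹ at the optimum with t quantiles.
Non-convergence raises `FitError` with the solver message.  On noiseless
Hill data the fit recovers (a, b) to 1e-6 (property-tested across
a ∈ [0.5, 5], b ∈ [5, 100]).

`HillCurve(fix_asymptote=False)` adds the asymptote as a third parameter,
F' = Emax · P^a/(b^a + P^a).  The package's convention is:

* fits against **model-predicted** F' use the constrained form — predicted
  F' is bounded by 1 by construction, so a free top is meaningless;
* the calibration fit against the **observed** F' of the small reference
  panel uses the free-asymptote form — observed F' is a noisy clinical
  derivative that can exceed 1, and with only 11 points a forced top of
  exactly 1 biases the slope upward (on the packaged panel: a = 2.95 forced
  vs a = 2.71 free, with fitted Emax = 1.03).

Only (a, b) are carried into the calibration either way.

Inter-assay calibration translates permeabilities measured in one
laboratory onto the scale the model was assessed against.  Two curves are
fitted: (a₁, b₁) to the model-predicted F' of the *full* panel passed to
`PappCalibrator.fit` (the predicted-side curve is a property of the
mechanistic model, not of the reference choice), and (a₂, b₂) to the
observed F' of the 11 reference drugs.  A measured P_app is then mapped by
matching Hill quantiles:

    P_calibrated = b₁ · (P / b₂)^(a₂/a₁)

which is algebraically hill⁻¹_(a₁,b₁) ∘ hill_(a₂,b₂): feeding P_calibrated
to the predicted-side curve returns exactly the observed-side curve's F'
(asserted to 1e-10 in a property test).  The map is strictly increasing and
sends b₂ → b₁.  The reference panel must be representative; the calibrator
warns if it fails to cover the full panel's permeability range to within an
order of magnitude at either end.

Reference fits are always recomputed from the packaged data, never
hard-coded.

## Clinical-data statistics

Per-drug clearances are pooled across studies with subject-number weights
(`weighted_mean`) and the population-form pooled SD

    σ = √( [Σ(σ_j² + x̄_j²)n_j − Σn_j · WX̄²] / Σn_j )

which equals the plain SD of the per-subject expansion (each study
contributing n_j subjects at its mean with its within-study variance) —
the oracle the property tests use.  Note this is the population form, not
the n−1 sample form; it is implemented verbatim and tested as such.

Between-study heterogeneity is screened with Cochran's Q (inverse-variance
weights) and I² = 100%·(Q − df)/Q clamped to [0, 100]; thresholds 0.5
(high) and 0.75 (very high) on the fractional scale.  Anomaly handling is
deliberately manual: `heterogeneity_report` ranks studies by standardized
deviation from the pooled mean for visual inspection, and nothing is
auto-excluded, because that judgement was made by eye in the source
workflow and automating it would silently change the data.

Normalised clearances (mL/min/kg, mL/min/1.73 m²) are converted to absolute
with the study's body size, or 70 kg / 1.73 m² when unreported.

## Ionisation and LogD at urinary pH

Ionisable centres are treated as independent Henderson–Hasselbalch sites at
pH 6.5; microstate probabilities are products of per-site terms.
Classification: Neutral if the fully un-ionised state exceeds 50%;
otherwise the most probable ionised microstate decides — only acids ionised
→ Acid, only bases → Base, both with zero net charge → Zwitterion, anything
else → Amphoteric.  This reproduces the curated class for all 45 packaged
drugs, including the four-site tetracyclines, though the independent-site
assumption is a simplification for such systems and the packaged classes
remain authoritative where they disagree.

LogD_6.5 is estimated from LogD_7.4 assuming only the neutral species
partitions; for monoprotic acids/bases the shift is the log-ratio of
un-ionised fractions at the two pHs (bounded by ±0.9 log units, the
water-side limit).  For multiprotic drugs the pKa nearest the 6.5–7.4
window is used; Neutral/Zwitterion/Amphoteric pass through unchanged.

## Evaluation metrics

Bias: geometric mean fold error, gmfe = 10^mean(|log₁₀(pred/obs)|) — ≥ 1,
swap-symmetric, scale-invariant, and over/under-predictions cannot cancel.
Success: % within k-fold (default 3, boundary inclusive).  Precision: RMSE
on **both** the log₁₀ scale and the raw mL/min scale.  The published
precision values this package is compared against print an RMSE formula on
the log scale but magnitudes (tens of mL/min) only consistent with the
linear scale; both flavours are therefore exposed and neither is treated as
a reproduction target.  R² is from the ordinary least-squares regression of
predicted on observed, untransformed.

Reports stratify by ionisation class and by observed-F_reab category
(low < 0.25 ≤ medium ≤ 0.75 < high; negatives → low).  With the packaged
printed-precision inputs the categories hold 15/12/18 drugs — two drugs sit
within 0.04 of the 0.75 boundary, so published stratum sizes based on
unrounded clinical values (17/12/16) differ by those boundary drugs.
Empty strata report NaN metrics, not zeros.

## Synthetic data generator

`generate_synthetic(n, seed, ...)` draws P_app log-uniform over
[0.1, 300]×10⁻⁶ cm/s (the ~3 decades a real Caco-2 panel spans) and f_u,p
uniform over (0.05, 1].  True F' comes from the mechanistic model itself —
or from a supplied Hill law, which is what the exact-recovery tests use —
and observed CL_R is the noiseless prediction times exp(N(0, noise_sd)).
The default noise_sd = 0.3 (natural-log scale) mirrors the ≈30%
between-study coefficient of variation typical of pooled clinical
clearances.  All randomness flows through one `numpy.random.default_rng(seed)`;
no global state.

What the generator emulates: the permeability span, the clearance bounds,
multiplicative observation noise.  What it does not: correlated errors
between P_app and CL_R measurements, transporter-mediated secretion,
ionisation-dependent permeability mis-scaling, or any chemical-series
structure.  Green tests on synthetic panels therefore validate the
numerical machinery and the statistical identities, not clinical
predictivity — that is what the packaged 45-drug panel tests are for.

## Numerical choices and degenerate inputs

* Fold-error metrics reject non-positive values naming the offending index;
  the equilibrium floor UF·f_u,p keeps mechanistic predictions positive.
* `freab_from_prime` raises when CL_filt ≤ UF·f_u,p (filtration below the
  urine-flow floor — unphysical input).
* The pooled-SD radicand is clamped at zero with a warning only when the
  negativity exceeds rounding noise (1e-9 relative).
* F_reab category boundaries: low is strict <0.25, high strict >0.75,
  medium inclusive.
* 3-fold success counts the boundary (≤ 3.0) as within.
* Closed-form chains are tested at 1e-9 relative; aggregate metrics against
  published values at ±5% relative, because the panel inputs are printed at
  three significant figures.

## Problem sizes

Everything runs at desk scale: the packaged panel has 45 drugs, property
tests use panels of 20–200 synthetic drugs, and the quadrature oracle uses
10⁵ grid points.  The full suite and the acceptance script each complete in
seconds on one CPU.

## Known limitations

* Static model; no urine-concentrating mechanism, pH gradient along the
  tubule beyond what the pH 6.5/7.4 permeability assay captures, renal
  metabolism, or active secretion.
* GFR is fixed at 120 mL/min for all drugs; observed F_reab of
  low-reabsorption drugs is sensitive to this choice.
* The microvilli factor is a single scalar applied uniformly to LoH/DT/CD.
* The calibration is a pragmatic inter-assay adjustment fitted to one
  dataset's reference subset, not a validated empirical predictor; applying
  it to external data requires re-fitting the observed-side curve.
* The geometric surface-area path requires user-supplied tubule dimensions.
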