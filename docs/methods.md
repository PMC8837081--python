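# Methods

## Optical model

The pseudophakic eye is modelled with thin-lens vergence optics: a
spectacle correction at vertex distance 12 mm, a single refracting
corneal surface, and a thin IOL at the estimated effective lens position
(ELP, `ACDest`), all in media of refractive index `na = 1.336`, with the
corneal vergence terms using `nc = 1.333`. Axial length from optical
biometry is adjusted for retinal thickness, `LOPT = L + 0.65696 −
0.02029·L`. The predicted spherical-equivalent refraction for an
implanted power `LP` is the SRK/T closed form quoted in the README; we
verified during development that it is numerically identical (to below
1e-9 D) to root-finding on the explicit vergence chain, and the test
suite keeps that dual-route check.

Double-K separation: the ELP regression receives only the pre-surgery
corneal power `Kpre` (the no-history constant 43.86 D unless overridden),
while the vergence terms receive the measured post-LASIK radius
`rpost = 337.5/Kpost`. The ELP chain is the published SRK/T sequence —
`LCOR` (identity up to 24.2 mm, quadratic −3.446 + 1.715·L − 0.0237·L²
above), corneal width `Cw = −5.41 + 0.58412·LCOR + 0.098·K`, corneal
height `H = rpre − sqrt(rpre² − Cw²/4)`, `ACDconst = 0.62467·A − 68.747`,
`offset = ACDconst − 3.336`, `ACDest = H + offset`. All coefficients are
surfaced in `SrktInternals` so an audit can override any of them.

The power formula is the exact algebraic inversion of the prediction
formula at the effective target `DR − C`; a property test checks the
round trip to 1e-9 D over randomized valid biometry, and with
`Kpre = Kpost`, `C = 0` the chain collapses onto an independently coded
classical single-K SRK/T.

## The C-factor

Myopic ablation raises the anterior/posterior radius ratio above the
normal ~1.19, and the double-K prediction error grows with it. The
correction is affine in the ratio, `C = slope·ratio + intercept`, with
the shipped calibration `slope = 3.28 D` per unit ratio and
`intercept = −4.00 D` (30-eye calibration, Pearson r = 0.678). At the
calibration cohort's mean radii (8.73/6.33 mm) this gives +0.52 D; the
correction crosses zero at ratio 1.2195. Recalibration is ordinary least
squares of the double-K prediction error (actual − predicted) on the
ratio; the paper-style "best fit" is not further specified, so OLS is the
design choice, with the Pearson correlation and its two-sided p attached
to the results object. Robust or weighted variants are deliberately not
defaulted.

## Sign and selection conventions

Refractions are spherical equivalents at the spectacle plane, myopia
negative. Prediction error is actual minus predicted. `select_iol_power`
rounds the exact power to a manufactured step (default 0.5 D); an exact
tie rounds to the *higher* power, leaving the more myopic residual — the
conventional safety preference after myopic LASIK — and both the step and
the behaviour are configurable by passing a different step.

## Numerical choices and degenerate inputs

- Corneal-height radicand: when `Cw²/4 > rpre²` the square-root argument
  is clamped to zero (`H = rpre`) with a runtime warning, matching common
  SRK/T implementations; this only occurs for extreme synthetic eyes.
- Geometry validity: the vergence formula degenerates as the lens plane
  approaches the retina, so `LOPT − ACDest > 0.5 mm` is required;
  violations raise `InvalidGeometryError` rather than returning a number.
- Keratometry conversions require strictly positive inputs; the
  radius-to-power map is the exact inverse of power-to-radius.
- Wilcoxon signed-rank comparisons drop zero differences, use the exact
  null for up to 25 non-zero pairs and a normal approximation with
  continuity correction above; an all-zero difference vector returns
  p = 1 with a warning. Fisher tests use the conventional two-sided
  definition (sum of tables no more probable than the observed one).
  Band membership is inclusive (|error| ≤ threshold). Bonferroni's `m`
  is always an explicit argument; in the comparison table it defaults to
  the number of comparator methods.

## Synthetic cohorts

`CohortSpec` encodes the two reported patient groups as range-truncated
normal marginals (rejection sampling): the 30-eye calibration group
(axial length 26.75 ± 1.67 mm in 24.81–29.63, mean K 38.90 ± 2.35 D,
posterior radius 6.33 ± 0.26 mm) and the 59-eye validation group
(27.01 ± 1.94 mm in 23.99–32.76, 38.95 ± 2.54 D, 6.36 ± 0.29 mm). The
anterior radius is the keratometric radius of the drawn K plus
N(0, 0.05 mm) jitter, emulating the small systematic disagreement between
interferometer-derived and Scheimpflug-measured radii visible in the two
groups' means (8.68 vs 8.73 mm). The implanted power is the ISS
emmetropia power rounded to 0.5 D steps (the surgeons' target policy is
not reported; emmetropia is the modelling choice, configurable via
`target_refraction_d`). The "actual" refraction is the double-K
prediction plus the ground-truth C-law (default slope 3.28, intercept
−4.00) plus N(0, noise_sd) with noise_sd = 0.35 D by default, chosen so
the calibration-recovery experiment has realistic residual scatter. The
A-constant of the clinical IOL model is unpublished; the generator uses
118.4, a typical monofocal value, while the optics functions require the
A-constant explicitly.

What the generator does *not* emulate: measurement error in axial length,
correlation between axial length and keratometry in myopes, ablation-zone
decentration, the joint distribution of anterior and posterior radii
(they are drawn independently apart from the K-derived anterior radius),
or longitudinal refractive change. Passing tests therefore demonstrate
internal consistency of the formulas and the calibration machinery under
the reported marginal distributions, not clinical accuracy on real eyes —
the clinical per-eye data are not published, so outcome-level numbers
(mean error, percentage bands) from synthetic cohorts are illustrative
only.

## Problem sizes

Property suites run 1000 randomized eyes for the inversion and degeneracy
checks, 300 eyes for calibration recovery (with 30 and 3000 used to show
the error shrinking), 59 eyes for evaluation flows, and full enumeration
for the exact-test oracles (all sign assignments up to n = 12; all 2×2
tables with total n ≤ 30). These sizes make the whole suite run in about
a minute on one core.

## Known limitations

- The C-factor default is a 30-eye calibration for one IOL model in one
  population; refitting is recommended for other lenses or demographics.
- Single-K SRK/T weaknesses inherited by the chain (ELP regression
  behaviour at extreme axial lengths) are mitigated but not removed by
  fixing Kpre.
- Toric/astigmatic planning, thick-lens and ray-tracing models are out of
  scope.
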