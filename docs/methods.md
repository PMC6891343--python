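# Methods

## Physical model

A leaf in a 2.55 THz transmission beam attenuates the source mainly through
its liquid water. The measured quantity is the optical depth
τ = ln(I₀/I_Tr), with I₀ the incident intensity (mean of one reading before
and one after the leaf measurements) and I_Tr the transmitted intensity
(mean over four blade positions; two for the small-leaved *Q. suber*).
Under Beer–Lambert attenuation, τ = α·d_w with α the water absorption
coefficient and d_w = M_w/(ρ_w·L_A) the effective water thickness — the
leaf's water volume spread over its projected area. Eliminating d_w:

    τ·L_A = C₁·M_w + C₀

with C₁ = α/ρ_w for pure water and C₀ absorbing residual dry-matter
absorption/scattering. Defaults α = 500 cm⁻¹ and ρ_w = 1000 mg cm⁻³ give an
implied pure-water slope K = 0.5 cm² mg⁻¹; fitted species slopes
(0.31–0.47 cm² mg⁻¹) sit below it, consistent with part of the attenuation
budget going to dry matter and wax rather than water. Scattering is treated
as negligible at this wavelength; only the single 2.55 THz operating point
is modeled (no absorption spectrum).

### Per-leaf optical depth

Intensities are pooled **before** the log: τ = ln(mean I₀ / mean I_Tr).
This mirrors the measurement protocol's definition of I₀ and I_Tr as
averages. The alternative — average of per-point ln(I₀/I_Tr,i) — is exposed
as `tau_from_transmission(..., method="per_point")`; by concavity of the
log the pooled value is never larger (Jensen), and pooling is markedly more
robust when individual transmitted readings approach the detector noise
floor, because positive noise excursions keep the *mean* intensity well
defined while a single near-zero reading would blow up its own log.
Transmitted intensity above incident produces τ < 0 with a warning rather
than an error: under drift and detector noise this is physically possible,
and a calibration pipeline must tolerate it rather than censor it.

## Calibration and inversion

Per species, ordinary least squares of y = τ·L_A (cm²) on x = M_w (mg):
slope C₁, intercept C₀, their standard errors and covariance, R²,
adjusted R² (one regressor: 1 − (1−R²)(n−1)/(n−2)), residual SD with n−2
degrees of freedom, and a two-sided Pearson test (t transform, n−2 df,
default α = 0.05, no multiplicity correction across the reported
regressions). The zero-intercept form τ·L_A = K·M_w is fitted as
K = Σxy/Σx². Regression direction is fixed — τ·L_A is the response, M_w the
predictor — and the nondestructive inversion is algebraic, not a reverse
regression:

    M̂_w = (τ·L_A − C₀)/C₁

Prediction variance combines, to first order (delta method), the new
observation's residual scatter with the sampling covariance of (C₀, C₁):

    Var(M̂_w) = [σ_res² + se(C₀)² + M̂_w²·se(C₁)² + 2·M̂_w·cov(C₀,C₁)] / C₁²

with t(n−2) intervals. Negative predictions (τ·L_A < C₀) are returned
as-is with a warning; truncating at zero would bias validation statistics.
A non-positive fitted slope raises: such a calibration is not invertible.

Species comparisons use Tukey–Kramer all-pairs tests (valid at unequal n)
via statsmodels, with a compact letter display assigned by the standard
insert-and-absorb algorithm; letters are ordered by descending group mean.
If the pooled within-group variance is exactly zero (degenerate synthetic
fixtures), pairs differ iff their means differ. Tukey letters are computed
on raw values.

## Leaf area

Two paths to the projected blade area, both in a 0-based pixel frame
(origin top-left, x = column, vertices at pixel centers):

- **Manual**: physical scale from a known length (cm/px = real/pixels),
  then the shoelace formula on the polygon outline, orientation-independent
  via absolute value. Self-intersecting outlines are rejected (shapely
  validity test); they indicate tracing errors, not measurable blades.
- **Automatic**: threshold a greenness index — excess-green 2G−R−B by
  default (robust to background tint), or Otsu on the green channel with
  the darker side as foreground — keep the largest 8-connected component,
  fill interior holes. Hole filling is unconditional: blades are simply
  connected, and specular highlights must not punch holes. Projected area
  only; curvature, perspective and petiole handling are out of scope.

## The synthetic study

No raw per-leaf data are published for this design, so validation runs
against a generator that reproduces the published summary statistics for
the six species: marginal means/SDs of water mass, leaf area and dry mass;
the per-species calibration slopes; the across-leaf optical-depth
dispersion; and the design's leaf counts (11, 10, 7, 10, 11, 10 = 59).

**Marginals.** (M_w, L_A, LDM) are jointly lognormal, moment-matched so the
published means/SDs are exact (μ = ln(m²/√(v+m²)), σ² = ln(1+v/m²)).
Lognormal rather than normal because several species have SD ≈ half the
mean (C. avellana M_w 407 ± 221 mg); a normal would need truncation at
zero, distorting the moments. A consequence: the generator matches the
marginals of L_A and LDM, so its mean per-leaf SLA (a ratio) differs
slightly from the published ratio summaries — no joint data exist to match
further.

**Joint structure.** The log-scale correlation matrix chains
M_w—L_A—LDM: corr(ln M_w, ln L_A) = corr(ln L_A, ln LDM) = ρ and
corr(ln M_w, ln LDM) = ρ², positive definite for every |ρ| < 1. The
published tables fix each species' τ dispersion, and since
τ = K·M_w/L_A is lognormal with log-variance σ_m² + σ_l² − 2ρσ_mσ_l, the
τ coefficient of variation pins ρ analytically
(`allometric_corr_for_tau_dispersion`):

    ρ = (σ_m² + σ_l² − ln(1 + cv_τ²)) / (2σ_mσ_l)

The shipped defaults use this per species (0.75–0.995). Two species
(*Q. suber*, *Q. ilex*) have published τ dispersions tighter than any
correlation of their published marginals allows (the formula yields ρ > 1);
for them ρ is capped at 0.995, the closest achievable. A generic
uncalibrated `SpeciesParams` defaults to ρ = 0.8. Note also that the
published per-species mean τ is not exactly K·(mean M_w)/(mean L_A) of the
same tables (e.g. *Q. suber* 4.44 derived vs 5.42 reported); the generator
is anchored on the mass/area marginals and slopes, so its τ means sit up to
~20% below the reported ones for those species.

**Instrument noise** (`InstrumentParams`, all configurable): incident
readings carry multiplicative drift (rel. SD 0.01 per reading); per-point
optical depth is τ·(1+η), η ~ N(0, 0.08), modeling within-blade water
heterogeneity plus positioning; transmitted readings get additive detector
noise (SD 0.001·I₀) and are clipped at a positivity floor (10⁻⁶·I₀) with a
warning — at τ ≳ 7 the signal falls below the noise and the instrument's
dynamic range is genuinely exhausted. These defaults put the instrument's
contribution to across-leaf τ SD near 0.2, small against the biological
part, landing total dispersion in the published 0.2–0.8 range for most
species.

**Seeding.** One master seed; species i's leaf sample uses
`SeedSequence(master, spawn_key=(i, 0))` and leaf j's measurement
`(i, 1+j)`, so any subset regenerates independently and byte-identically.

**Renderer.** Leaf images are green superellipses (default exponent 2 =
ellipse, aspect 1.6) of exactly the leaf's area on white background, 3×3
subpixel anti-aliasing, optional speckle; scale auto-chosen so the major
axis spans ~400 px, with a hard floor of 50 px across the minor axis. The
renderer returns the analytic area as ground truth. Real leaf images have
lobed margins, petioles, veins, shadows and non-white backgrounds; passing
segmentation tests on these fixtures validates the thresholding/labeling/
hole-filling machinery, not robustness to field imagery.

### What the simulations do and do not show

Zero-noise, the full chain (simulate → CSV → calibrate → invert) is an
exact identity to ≤10⁻⁸ relative error — the pipeline adds no numerical
distortion. At default noise and design leaf counts, fitted slopes recover
the generating values (Monte-Carlo mean within ~7% at n ≈ 10, within 2% at
n = 500; the small residual bias is the Jensen effect of pooling noisy
exponentials before the log) and per-species adjusted R² is typically
0.95–0.99. Two caveats are inherent rather than implementation artifacts:

- At the design sample sizes (7–11 leaves), a species with a narrow water
  mass spread (*O. carpinifolia*, CV 0.20) or few leaves and the 2-point
  protocol (*Q. suber*) shows substantial sampling variation in R̂²; the
  probability that *all six* species clear adj R² > 0.85 in one simulated
  study is ≈0.85–0.90, not 1. The published single-study values (0.86–0.99)
  are consistent with this spread.
- The τ noise is multiplicative in M_w, so classical OLS slope SEs
  under-cover: 3-SE coverage of the generating slope is ~93% (≈96% with
  HC3), not the nominal ~99.7%. The prediction intervals inherit a mild
  version of this optimism.

## Numerical choices and degenerate inputs

- Validation errors are a typed hierarchy under `LeafTHzError`; physically
  suspicious but possible situations (negative τ, clipped readings,
  negative predicted mass) warn instead of raising.
- Protocol checking (2 points only for small-leaved species) is strict by
  default, relaxable with a flag.
- The measurement CSV dialect is fixed (comma, point decimal, UTF-8,
  header); bad rows are rejected individually with row-numbered messages
  while the rest of the file loads. Floats round-trip exactly through the
  dialect.
- Reports are deterministic: JSON with sorted keys, no timestamps; rendered
  tables use two decimals. Calibration-model JSON records an input digest
  for provenance (a timestamp can be supplied explicitly but is off by
  default to keep repeated runs byte-identical).
- With a single species, Tukey letters are omitted with a note; flat
  responses report r = 0, p = 1 rather than NaN.

## Problem sizes

The default validation workloads are sized for an ordinary laptop core:
moment checks at n = 10⁴ leaves, fit-quality replication at 100 studies of
59 leaves, slope-recovery at ten replicates of n = 500, coverage checks at
200 fits, and property suites at 300–10⁴ random cases; the full test suite
runs in well under a minute.
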