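# Methods

## The model

A protein P binds a ligand L in a single step, P + L ⇌ PL, with dissociation
constant K_D.  At total protein concentration [P]_T and ligand:protein molar
ratio x = [L]_T/[P]_T, mass action gives the bound fraction as the physical
root of the binding quadratic,

    f(x) = ½[(1 + K_D/[P]_T + x) − sqrt((1 + K_D/[P]_T + x)² − 4x)].

The implementation evaluates the algebraically equivalent form
f = 2x / (A + sqrt(A² − 4x)) with A = 1 + K_D/[P]_T + x, which is free of the
subtractive cancellation the root expression suffers when K_D ≫ [P]_T; it
agrees with an independent bisection solver of the mass-action balance to
1e−9 over eight decades of K_D (tested).

Two observational encodings of f(x) are supported, corresponding to the two
exchange regimes of two-site chemical exchange:

* **Fast exchange** (k_ex ≫ Δν, the peak separation in s⁻¹): one
  population-averaged peak per probe moves with saturation, so the composite
  CSP follows Δδ(x) = Δδ_max·f(x).  Both parameters (K_D, Δδ_max) are fitted
  per probe by Levenberg–Marquardt least squares (lmfit), bounded positive,
  initialised at Δδ_max⁰ = 1.1 × the largest observed CSP and K_D⁰ = [P]_T ×
  (ratio at half-maximal CSP).  At least three distinct nonzero ratios are
  required.
* **Slow exchange** (k_ex ≪ Δν): separate free- and bound-form peaks whose
  volumes redistribute as 1 − f(x) and f(x).  Two per-point estimates are
  formed from peak volumes: the free route 1 − I_P(x)/I_P(0) and the bound
  route I_PL(x)/I_PL(x_max), which normalises by the bound-form volume at
  the final titration point rather than the apo intensity and therefore
  assumes the endpoint is essentially saturated.  A route is used only when
  both volumes involved carry relative errors at or below a threshold
  (default 0.20; the threshold is a data-quality gate, not a statistical
  weight).  Raw route values outside [−0.05, 1.05] are discarded as
  unphysical; surviving routes are averaged with equal weight (the
  historical combined estimator is exactly this arithmetic mean), and the
  single surviving route is used alone near the titration ends where the
  weaker peak is unquantifiable.  K_D is then fitted to the combined f(x).

### Endpoint-saturation correction (slow exchange)

The bound route is exact only if f(x_max) = 1.  At a realistic design
(K_D = 53 µM, [P]_T = 160 µM, x_max = 16) the endpoint saturation is 0.978,
which inflates every bound-route estimate by ~2% and biases the fitted K_D
low by ~7–15%.  `SlowExchangeModel.fit` therefore iterates a self-consistent
correction by default: fit K_D, rescale the bound-route estimates by
f(x_max; K_D), refit, until K_D is stationary (tolerance 1e−10 relative,
typically 3–5 iterations).  At the true K_D the rescaled estimates equal
f(x) exactly, so the noiseless round trip through the generator closes to
machine precision.  With the correction disabled, the normalisation point
x_max is excluded from the fit instead, since its bound-route value is
identically 1 by construction and carries no information.

### Aggregation

Per-probe K_D values are averaged to a mean ± sample SD (n−1), with the
selection rule recorded verbatim in every report.  Defaults differ by
regime, for a reason:

* *Fast exchange*: probes whose endpoint composite CSP exceeds the
  10%-trimmed mean of all probes.  A probe with a near-zero Δδ_max carries
  no curvature information and its K_D estimate diverges under noise; the
  trimmed-mean gate removes exactly those probes.
* *Slow exchange*: all successfully fitted probes.  Here every probe is
  equally informative (the data are volume ratios, independent of shift
  magnitudes), and the alternative — selecting on the endpoint bound-peak
  volume — conditions on the estimator's own normalisation denominator:
  probes kept preferentially carry upward volume noise at x_max, deflating
  their fractions and inflating K_D by ~16% at 5% volume noise (measured in
  simulation).  Both rules remain selectable.

## Composite CSP and classification

Δδ = sqrt(ΔδH² + (s_X·ΔδX)²) with s_C13 = 0.18 and s_N15 = 0.15
(configurable).  It is a weighted Euclidean norm: nonnegative, zero only at
zero, homogeneous of degree one — properties the test suite asserts.
Classification thresholds are the 10%-trimmed mean of all composite CSPs and
that mean + 1 SD, where the trimming removes ⌊0.1·n⌋ values from *each* tail
and the SD is the sample SD of the trimmed set (full-set SD selectable).  A
residue is categorised by its most-shifted methyl ("at least one methyl
group" rule), so the two categories nest.  The trimmed statistics are
computed over methyl groups (the plotted unit), not residues.

## Two-ligand comparison

Endpoint CSP records of the two ligands are matched by probe.  Magnitudes
are compared by ordinary least squares of ligand-B on ligand-A composite
CSPs (free intercept by default, through-origin selectable; R² is the
squared Pearson correlation, checked against the closed-form normal
equations to 1e−12).  Directions are compared in the s_X-scaled 2D plane —
the same space in which the composite CSP is a norm — via the dot product
and cosine; a cosine is reported only when both magnitudes exceed a noise
floor (default 0.005 ppm composite), because the direction of a vector
smaller than the noise is meaningless.

**Magnitude outliers.** The probes being hunted are exactly the points that
drag an OLS line, so flagging measures residuals from a Theil–Sen fit (with
the intercept taken as the median residual about the slope; the conventional
median(y) − slope·median(x) intercept shifts under one-sided contamination).
Residuals are centred at their median, scaled by 1.4826 × MAD to estimate
σ under Gaussian noise, and flagged beyond a cutoff.  The default cutoff is
multiplicity-calibrated: k = Φ⁻¹(1 − α/2n) with α = 0.001, ≈ 4.3 robust SDs
at n = 70, chosen so a fully clean dataset is declared clean with
probability 1 − α regardless of probe count, while a programmed displacement
of 10 × the shift noise sits at ~12 robust SDs and is always caught.  A
fixed per-probe multiplier (the classic 3 × MAD) is available by argument;
with dozens of probes it false-flags roughly one clean probe per few
datasets, which is why it is not the default.

**Direction reversals.** Probes with a defined cosine below a threshold
(default −0.2).  Near the noise floor, detection is inherently undecidable:
a true reversed vector just above the floor can measure below it and vice
versa.  The generators' truth tables therefore expose
`detectable_reversals(floor)`, the programmed set restricted to probes whose
noise-free magnitude clears the floor, and the recovery guarantees are
stated for reversals clearing the floor by ≥ 3 × the per-component noise.

## Kinetics

Exchange classification compares k_ex/Δν with thresholds r_slow = 0.1 and
r_fast = 10 (inclusive at the boundaries; configurable).  A slow-exchange
observation bounds k_off ≪ Δν and hence k_on = k_off/K_D in the same
direction — e.g. K_D = 53 µM with Δν ~ 50 s⁻¹ bounds k_on ≪ ~9.4 × 10⁵
M⁻¹s⁻¹, far below diffusion control.  Turnover is the negative least-squares
slope of remaining substrate concentration (normalised integral × initial
concentration) versus time over the early linear phase (points with
normalised integral above 0.8 by default), divided by the enzyme
concentration, in molar equivalents of substrate per enzyme per hour;
`project_conversion` inverts it into a percent-converted projection, capped
at 100%.  A significantly increasing substrate integral (slope > 2 SE)
raises a data-quality error rather than returning a negative rate.

## Synthetic data: what it emulates, and what it does not

The generators emulate the statistical structure the analysis assumes:
bound-state shift vectors with log-normally distributed composite magnitudes
(median = `bound_shift_scale`, log-SD 0.6 — the heavy right tail of real CSP
profiles) and directions uniform on the circle; additive Gaussian shift
noise (defaults 0.002 ppm ¹H, 0.01 ppm ¹³C, typical HMQC precision);
multiplicative log-normal volume noise of unit mean (CV default 5%, echoed
into `volume_rel_err`); and a visibility floor (5% of the apo volume) below
which peaks are omitted, emulating peaks too weak for accurate volume
quantification near the titration ends.  Default designs: slow exchange at
K_D = 53 µM, [P]_T = 160 µM, x ∈ {0, 1, 2, 4, 8, 16}; fast exchange at
K_D = 1.6 mM, [P]_T = 200 µM, x ∈ {0, 0.5, 1, 2, 4, 8, 10} with
Δδ_max-scale 0.12 ppm.  Two-ligand datasets default to 70 probes — the scale
of a full ILV-methyl spectrum of a RecA-like domain — with ligand-B vectors
equal to `gradient` × ligand-A, programmed outliers displaced along their
own direction by `outlier_displacement` (alternating sign, downward only
when the result stays above the direction noise floor, so a displacement can
never fold a vector through zero), and programmed reversals sign-flipped.
All draws descend from a single integer seed; equal seeds give bit-identical
output, and every generated series passes `validate_series` with no
findings.

Not emulated: intermediate-exchange lineshapes, differential relaxation
between free and bound forms (volumes here are strictly proportional to
populations), probe-to-probe volume heterogeneity, baseline or overlap
artefacts, and sample dilution across titration points (per-point protein
concentrations are carried through the manifest but default to constants).
Passing tests therefore certify the estimators against their own model
assumptions, not against spectral-processing artefacts of real data.

## Numerical choices

* Isotherm in the cancellation-free form; discriminant clamped at 0.
* Slow-exchange K_D identifiability requires at least one nonzero point with
  0.02 < f < 0.98; a titration whose every nonzero point has f > 0.98 raises
  an "unidentifiable" error advising lower ratios.
* Fractions are clipped to [0, 1] only at the fit stage; raw route values
  are retained in the estimate records.
* Reports render floats at 6 significant digits and sort rows by residue
  number then site label, making reruns byte-identical under fixed seeds.
* Trimmed-statistics tie-break: the trim count is ⌊n·fraction⌋ per tail.
* Probe identifiers are canonicalised as one-letter code + residue number +
  optional a/b, with "a" the lower-¹H-shift methyl of a Leu/Val pair.

## Problem sizes

The recovery checks run 50 seeded replicates per design (30 probes each):
slow exchange recovers the generating K_D = 53 µM to within a few percent in
the grand mean (tolerance held: 15%), fast exchange recovers K_D = 1.6 mM to
~0.5% in the grand mean (tolerance held: 20%).  The acceptance script
repeats the fast-exchange recovery (50 × 30 fits, ~3 s) plus the closed-form
saturation and gradient calculations.

## Known limitations

* The slow-exchange saturation correction assumes one shared [P]_T per
  series when rescaling; per-point concentrations enter f(x) but the
  correction uses the series-level value.
* The Sparky importer takes Data Height as a volume surrogate with a
  configured default relative error; no volume integration is attempted.
* No global multi-probe shared-K_D fit: per-probe fits are averaged, so the
  reported SD mixes fit noise with genuine probe-to-probe variation.
* The expected-gradient calculation treats both ligands' bound-state shift
  patterns as identical by hypothesis; it is a null model, not an estimate.
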