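# Methods

This note documents the models and procedures implemented in
`normsupp`, the choices behind their defaults, and what the synthetic
generators do and do not emulate.

## The normalization model (`normalization_model`)

The population response to a drifting grating is

    R(x, theta) = g_r * E(x, theta) / (S(x, theta) + sigma)

where the excitatory drive `E` and suppressive drive `S` are the same
effective-contrast field pooled with narrow and broad Gaussians,
respectively, and `sigma` (the semi-saturation constant) sets
sensitivity at low input strength.  The effective contrast is
`(c * g_c) ** n` — contrast `c` in [0, 1], input gain `g_c`, and an
expansive response exponent `n` (default 2, an energy-type
nonlinearity typical of early visual cortex).  `g_r` is the output
(response) gain.

**Geometry.** The stimuli and the model are circularly symmetric, so
fields are stored as their radial section through the stimulus center
(a symmetric 1-D profile over positions in degrees) crossed with a
motion-direction axis on [0, 360).  Spatial pooling is a genuine 2-D
operation: the section is rotated into its circular 2-D field (linear
interpolation in radius) and convolved with a unit-volume separable
2-D Gaussian, and the pooled central row is returned.  The 2-D
geometry is quantitatively essential: pooled drives grow with stimulus
*area*, so the drive ratio between the 1 and 2 degree stimuli
approaches 4 in the broad-pool limit, not the factor-2 ceiling a 1-D
line model imposes.  That head-room is what lets the model produce
suppression and summation as strong as observed (size indices near
-0.2 to -0.45 and +0.24 to +0.26) rather than marginal effects.
Direction pooling is a wrapped (circular) Gaussian; for a single
grating the drive is uniform in direction and this pooling is inert,
but the axis keeps the broader suppressive feature pooling
representable for multi-component stimuli.

**Stimulus drive.** A grating of diameter `d` in an aperture whose
edge is blurred with a Gaussian of SD `edge_sd` (default 0.25 deg) has
the closed-form radial profile of a boxcar convolved with that
Gaussian (an erf ramp), scaled by the effective contrast.

**Numerics.** Grids default to 0.05 deg spacing with half-extent
radius + 3 suppressive SDs; pooling kernels are truncated at +/-5 SD
and renormalized to unit sum (boundary leakage below 0.1% for interior
fields).  Oversized stimuli and kernels wider than the grid raise
errors rather than truncate silently.

**Readout and thresholds.** A winner-take-all readout takes the field
maximum.  For small stimuli this is the center response; for large
flat-top stimuli the response forms a shallow symmetric annulus just
inside the aperture edge (the broad suppressive pool is truncated
sooner than the narrow excitatory pool there), so the maximum can sit
slightly off-center — a real regime, not a discretization artifact.
An asymmetric field (no mirror twin) triggers a warning.  Predicted
duration thresholds follow `threshold = criterion / peak_response`,
with one criterion per contrast (defaults 105 at 98% contrast, 5 at
3%), chosen so the baseline model prints threshold ranges typical of
this paradigm (roughly 30 -> 82 ms with size at high contrast, 109 ->
60 ms at low).

**Size indices.** `SI = log10(threshold_smaller) -
log10(threshold_larger)`; negative = suppression, positive =
summation.  In the model table the SI is computed from the gain-free
peak ratio — `criterion` and `response_gain` cancel analytically in
the log difference — so the invariance of SIs under criterion or
response-gain scaling is exact to the bit, not just approximate.  The
reapplication of response gain to the scalar peak is itself exact
because rounding is monotone (the field max commutes with positive
scaling).

**Default parameters** (all config keys; spatial values are assumed,
i.e. chosen by this package, not published):

| parameter | default | units | why |
|---|---|---|---|
| sigma | 0.01 | response units | within two orders of magnitude of the 3% contrast, the regime where low-contrast summation emerges |
| exc_space_width | 0.4 | deg (SD) | comparable to the smallest (1 deg) stimulus |
| sup_space_width | 1.0 | deg (SD) | broader than excitation; in the area-linear regime for the 1-2 deg pair |
| exc/sup_feature_width | 30 / 90 | deg direction | suppressive pooling broader in feature as well |
| contrast_gain_exponent | 2.0 | — | expansive contrast response; without it no sigma simultaneously yields strong high-contrast suppression and low-contrast summation |
| criterion | 105 (98%), 5 (3%) | response x ms | threshold ranges typical of this paradigm; lower criterion at low contrast |

**Model variants** (`config.PRESETS`): `lorazepam_contrast_gain`
(input gain 0.7, exponent raised to 2.6) raises thresholds mostly for
small stimuli, weakening suppression; `lorazepam_response_gain`
(output gain 0.7) raises all thresholds and moves no SI;
`criterion_shift` (criterion x0.8) lowers all thresholds and moves no
SI — the model-level account of why higher baseline GABA+ can improve
overall performance without touching suppression strength.

## Psi staircase (`staircase`)

Bayesian adaptive placement over a Weibull threshold/slope grid:
alpha on 40 log-spaced points in 3-500 ms, beta on 25 log-spaced
points in 0.5-16, uniform prior, candidate durations 60 log-spaced
points in 6.7-333 ms.  Each trial presents the duration minimizing the
expected entropy of the joint posterior (ties break toward shorter
durations); updates are Bayes rule in log space (no underflow over at
least 1000 trials).  Guess and lapse are fixed at 0.5 and 0.04 inside
the likelihood.  Grid ranges are implementation choices (the threshold
grid spans the 500 ms exclusion bound); lapse is not marginalized.

At 300 trials the posterior-mean threshold tracks an independent MLE
refit of the same trials closely; both carry irreducible sampling
error of up to ~15-20% in occasional runs, so recovery assertions are
stated as a median (<10%) plus a hard cap (<20%), not a per-run 10%.

## Psychometric fitting (`psychometrics`)

`P(correct | x) = 0.5 + 0.46 * (1 - exp(-(x/alpha)^beta))`.  Fits
maximize the Bernoulli likelihood over (log alpha, log beta) with
Nelder-Mead from a fixed 5x5 log-spaced start grid (the three best
starts by initial likelihood are polished; tolerance 1e-8), making the
fit deterministic.  The 80%-correct threshold comes from the closed
form `alpha * (-ln(1 - (0.8-gamma)/(1-gamma-lambda)))^(1/beta)`.
All-correct or all-incorrect data are flagged degenerate and excluded;
estimates outside (0, 500] ms are excluded, never imputed.  The scale
is identified quickly (±5% at ~2000 trials) but the shape is not (its
sampling SD is ~20% there); slope assertions require much larger
samples.  Runs are fitted separately and run thresholds combined by
geometric mean; drug effects are within-subject (drug - placebo)
differences on matched conditions.

## fMRI ROI analysis (`fmri_roi`)

Blocked alternating-size designs: 25 blocks of 10 s at TR 2 s (125
samples), big-stimulus blocks annotated.  Epochs span [-4 s, block end
+ 2 s); a single run baseline is the mean over all epochs' [-4, 0) s
windows — in this design that window lies in the preceding
small-stimulus block, which is exactly the intended reference.  Percent
signal change is `100 * (x - b) / b` (scale-invariant), and the
response measure is the mean psc at onset-relative times `8 <= t < 12`
s (half-open on the TR grid: the samples at 8 and 10 s; edge handling
is a package decision since block timing is only defined to TR
resolution).  Aggregation is strictly nested means — epochs, then
hemispheres within run, then runs — and missing hemispheres average
over what exists, with a log note.

## MRS quantification (`mrs_quant`)

Averages whose frequency-correction magnitude exceeds mean + 3 SD
(computed once, population SD) are rejected; correction itself is out
of scope and the magnitudes are inputs.  3 Hz exponential line
broadening is applied as convolution with a unit-area Lorentzian of
that FWHM (integral-conserving).  The GABA+ peak in [2.8, 3.2] ppm is
modelled as a Gaussian over a linear baseline; because the applied
broadening is known, the fitted model is that Gaussian convolved with
the known Lorentzian (a Voigt with fixed Lorentzian width), and the
reported integral is the underlying Gaussian's closed form
`amplitude * width * sqrt(2*pi)` — fitting the broadened peak with a
plain Gaussian would lose the Lorentzian wings (~11% of the area at
these linewidths).  Water near 4.7 ppm is a pseudo-Voigt
(`eta * Lorentzian + (1-eta) * Gaussian`, shared center/width)
parameterized directly by its area.  The ratio is corrected for voxel
composition by `raw / (f_gm + alpha * f_wm)` with alpha = 0.5 and CSF
assumed GABA-free; this simple form omits the relaxation/visibility
terms of full literature corrections, which affect the scale but not
the rank order across subjects (verified by a rank-preservation test).

## Synthetic data (`synthetic_data`)

Generators emit ground truth beside every dataset.

- **Observers** respond by the Weibull above with the scale set so
  P(correct) = 0.8 exactly at the condition's true threshold;
  condition thresholds come from the model's prediction table scaled
  by a per-subject ability factor.
- **Experiments**: 6 conditions (3%/98% x 1/2/12 deg) x 4 runs x 30
  staircase trials, plus 10 catch trials per run (big high-contrast,
  333 ms) answered correctly at 99%; condition order within a run is
  randomized.  Subject ability (log10 threshold offset, SD 0.15) and a
  GABA+ value (mean 1.0, SD 0.15, institutional units) are drawn
  bivariate-normal with correlation rho (default -0.46).  Because
  ability is a pure threshold scaling, it moves the geometric-mean
  threshold but no SI — reproducing, by construction, a GABA-overall
  performance association with no GABA-suppression association.  The
  lorazepam arm multiplies thresholds by 10^shift with shifts largest
  for the smallest stimuli (0.25/0.15/0.08 log10 by size).
- **BOLD runs**: the alternating block design convolved with a
  unit-gain double-gamma HRF on a baseline of 100, white noise 0.25%
  psc per TR (a realistic ROI-average level; ~40 voxels).  The HRF
  attenuates a 0.2% block-amplitude offset to ~0.14% in the peak
  window.
- **Spectra**: 2048 points over a 2 kHz width at 127.7 MHz; Gaussian
  GABA+ peak (SD 0.045 ppm) at 3.0 ppm, pseudo-Voigt water at 4.7 ppm,
  noise scaled by 1/sqrt(kept averages) from a single-average SD of
  25; per-average correction magnitudes |N(0,1)| with optional
  injected outliers.

What the generators do *not* emulate: serial dependencies and
fatigue/learning in behaviour, physiological (non-white, autocorrelated)
BOLD noise and motion, macromolecule contamination and baseline
distortions in spectra, and any spatial structure within ROIs.
Passing recovery tests therefore demonstrate correctness of the
analysis chain under the stated noise models, not robustness to every
artifact of real recordings.

## Statistics (`stats`)

Within-subject ANOVA uses the standard subject x cell means
decomposition, each effect tested against its own subject-by-effect
interaction (one or two factors); a constant outcome yields F = 0, and
a continuous-size linear trend is the centered contrast score tested
against zero (F = t^2).  Friedman's test is the rank-based companion,
and the reporting rule computes both and reports the larger p.
Permutation correlations shuffle one variable (default 10,000
iterations) with `p = #(|r_perm| > |r_obs|) / n_iter` — the strict
inequality, no +1 correction, exactly as the procedure is defined; the
conventional (b+1)/(m+1) estimator is available behind a flag.  The
minimum detectable correlation uses the Fisher z approximation
`r = tanh((z_{1-alpha/2} + z_power)/sqrt(n-3))`, which prints 0.52 at
n = 27 and 0.58 at n = 21 for 80% power at alpha 0.05 (two-tailed).
Median splits divide even samples exactly in half, resolving ties by
stable rank order with a log note.

## Problem sizes in the test suite

The acceptance checks run 100 replicate simulated experiments for the
psychophysics chain, 100 seeded spectra/BOLD runs, and 1000 null
datasets for permutation calibration — sizes at which every reported
rate is stable to a few percent while the whole suite stays fast.  The
null-uniformity check uses 1000 datasets rather than a minimal 200
because the KS distance of even a perfectly uniform 200-point sample
typically exceeds 0.05 (median ~0.059); at 1000 datasets the same 0.05
bound is a meaningful calibration test.

## Known limitations

- The spatial model is steady-state; stimulus duration enters only
  through the criterion rule, and no temporal dynamics are modelled.
- Model parameters are set by hand within the stated regime, not
  fitted to data; the package deliberately provides no optimizer.
- The readout's annulus maximum for large flat-top stimuli means
  "peak" and "center" responses differ slightly in that regime.
- The tissue correction is the simple alpha form; comparisons with
  literature values using fuller corrections are scale-shifted.
- Two-factor ANOVA requires complete crossed designs after listwise
  exclusion; no sphericity correction is applied (effects are tested
  against their own interaction terms).
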