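# normsupp

Analysis pipeline for spatial **surround suppression** and **summation**
in human motion perception: a divisive-normalization model of visual
cortex linked to psychophysical duration thresholds, blocked-design
fMRI suppression indices, and edited-MRS GABA+ measures — with
synthetic-data generators for every stage, so the full chain runs and
is testable at desk scale without any recorded data.

It is written for vision scientists who use the classic
motion-discrimination paradigm: briefly presented drifting gratings
whose direction is harder to judge when a high-contrast stimulus gets
*bigger* (suppression), and easier when a low-contrast stimulus gets
bigger (summation).

## The model

The population response to a grating is divisively normalized,

```
R = g_r · E / (S + σ)
```

where `E` and `S` are the same effective-contrast field
(`(c·g_c)^n`, exponent n = 2) pooled over a narrow excitatory and a
broader suppressive spatial extent (2-D Gaussians over the circular
stimulus), and σ is the semi-saturation constant.  A winner-take-all
readout takes the peak response, and the predicted duration threshold
for motion discrimination is

```
Threshold = Criterion / R_peak .
```

Suppression versus summation needs no separate mechanisms: at high
contrast the suppressive drive outgrows the excitatory drive with
stimulus size (R falls), while at low contrast `S ≪ σ` and R grows
with size until S catches up.  The effect of size is quantified by the
size index

```
SI = log10(threshold_smaller) − log10(threshold_larger)
```

(negative = suppression, positive = summation), which is analytically
invariant to the criterion and to response gain — the model-level
reason a criterion change can improve overall performance without
touching suppression strength.

The other stages are a Psi adaptive staircase (Bayesian
expected-entropy stimulus placement over a Weibull threshold/slope
grid), maximum-likelihood Weibull fits with fixed guess (50%) and
lapse (4%) rates and thresholds at 80% correct, percent-signal-change
peak responses of alternating-size blocked BOLD runs, Gaussian /
pseudo-Voigt peak quantification of edited spectra with α-based tissue
correction, and a statistics layer (repeated-measures ANOVA, Friedman,
permutation-tested Pearson correlations, correlation power analysis,
median splits).  See `docs/methods.md` for the full account.

## Worked example

Predict thresholds and size indices for the six standard conditions
(3% / 98% contrast × 1 / 2 / 12° diameter):

```
$ normsupp model predict --out pred.csv
 contrast  diameter_deg  peak_response  predicted_threshold_ms
     0.03           1.0       0.045729              109.339063
     0.03           2.0       0.079105               63.207519
     0.03          12.0       0.083143               60.137559
     0.98           1.0       3.482462               30.151082
     0.98           2.0       2.250295               46.660539
     0.98          12.0       1.275867               82.296997
 contrast pair  smaller_deg  larger_deg        si
     0.03  s-m          1.0         2.0  0.238007
     0.03  s-b          1.0        12.0  0.259630
     0.98  s-m          1.0         2.0 -0.189647
     0.98  s-b          1.0        12.0 -0.436081
```

At 98% contrast thresholds rise with size (SIs negative: suppression);
at 3% they fall (SIs positive: summation).  The same library functions
drive simulated experiments end to end:

```python
from normsupp.synthetic_data import PopulationSpec, gen_experiment
from normsupp.psychometrics import fit_trials_table, size_index_table

exp = gen_experiment(PopulationSpec(n_subjects=10, seed=0))
fits = fit_trials_table(exp.trials)                    # per-run Weibull fits
sis = size_index_table(fits, value="threshold80_ms")   # per-subject SIs
```

Other entry points: `normsupp staircase`-style simulation via
`normsupp synth experiment`, `normsupp synth bold` → `normsupp fmri`,
`normsupp synth spectrum` → `normsupp mrs`, and `normsupp power`
(minimum detectable correlation, e.g. `n=21: r=0.58`, `n=27: r=0.52`).

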