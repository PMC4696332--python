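# alphaband

Individualized EEG frequency-band anchoring and the **alpha3/alpha2 power
ratio**, an electroencephalographic biomarker of the risk that a patient
with mild cognitive impairment (MCI) will convert to Alzheimer's disease
(AD) — together with the cohort statistics used to evaluate such markers
and a synthetic EEG/cohort generator that makes every stage testable
without patient data.

## The science

Resting-state EEG band powers are conventionally computed over fixed
bands (e.g. alpha = 8–12 Hz), but alpha activity shifts between
individuals.  `alphaband` instead anchors every band to two
subject-specific frequencies read off the channel-averaged ("collapsed"
or global-field) power spectrum:

- **IAF** — the individual alpha frequency, the maximum-power peak in
  the extended alpha range 5–14 Hz;
- **TF** — the theta/alpha transition frequency, the power minimum
  between the theta and alpha bulges.

The individual bands are then

| band   | range                 |
|--------|-----------------------|
| delta  | [TF−4, TF−2)          |
| theta  | [TF−2, TF)            |
| alpha1 | [TF, (TF+IAF)/2)      |
| alpha2 | [(TF+IAF)/2, IAF)     |
| alpha3 | [IAF, IAF+2)          |

Relative powers are normalized by total power over 2–45 Hz, and the
prognostic markers are the **alpha3/alpha2** and **theta/gamma** relative
power ratios.  Subjects are stratified by alpha3/alpha2 into low
(< 1.0), middle ([1.0, 1.17)) and high (≥ 1.17) risk groups; the
high-ratio group carries the elevated AD-conversion risk.

The processing chain for one subject is: common-average re-reference →
consecutive 2-s epochs → threshold artifact rejection → per-epoch
Hann-windowed Welch spectra (0.5 Hz resolution) averaged over kept
epochs → collapse across the 19-channel 10–20 montage → anchor
detection → band powers → ratios → risk group.

The cohort layer provides the matching statistics: one-way ANOVA /
ANCOVA with Levene-gated post-hocs (Games–Howell under heterogeneous
variances, Bonferroni otherwise), Pearson correlations with
pairwise-complete deletion, chi-square tests for categorical variables,
and forward-stepwise canonical discriminant analysis on Wilks'-lambda
partial F (F-to-enter 1.0, tolerance 0.01) with canonical roots,
Bartlett tests, factor structure matrix and a resubstitution
classification table.

## Worked example

```python
from alphaband import generate_eeg, subject_pipeline, subject_preset

rec = generate_eeg(subject_preset("high-risk", seed=0), duration=300.0)
res = subject_pipeline(rec)
```

Running `python examples/01_single_subject.py` (the same computation)
prints:

```
epochs kept          : 150/150
transition freq (TF) : 7.0 Hz
alpha peak (IAF)     : 10.0 Hz
  delta   [  3.0,   5.0)  rel power 0.121
  theta   [  5.0,   7.0)  rel power 0.154
  alpha1  [  7.0,   8.5)  rel power 0.054
  alpha2  [  8.5,  10.0)  rel power 0.236
  alpha3  [ 10.0,  12.0)  rel power 0.302
  beta1   [ 12.0,  15.0)  rel power 0.017
  beta2   [ 15.0,  30.0)  rel power 0.040
  gamma   [ 30.0,  45.0)  rel power 0.024
alpha3/alpha2 ratio  : 1.277
theta/gamma ratio    : 6.515
risk group           : high
```

The generator's ground truth (IAF 10 Hz, upper-alpha dominant source) is
recovered: all 150 two-second epochs survive screening, the anchors land
on the true frequencies, and the alpha3/alpha2 ratio of 1.277 — within
0.03 of the preset's closed-form expected value — places the subject in
the high-risk tertile.

The other example scripts cover band construction from cohort-mean
anchors (`02`), outcome-group ANOVA and stepwise discriminant analysis
on a synthetic follow-up cohort (`03`), and the consistency of the
collapsed spectrum with frontotemporal/parietoccipital macroareas
(`04`).  A thin CLI wraps the same functions:

```bash
alphaband subject  --in rec.edf --out report/
alphaband cohort   --manifest subjects.tsv --out markers.tsv
alphaband simulate --out sim/ --seed 7
```

## Scope

MRI cortical-thickness estimation, SPECT processing and W-score
computation are out of scope; imaging-derived quantities enter only as
per-subject covariate columns in the cohort table.  Classification
accuracy is resubstitution (no cross-validation), matching the classic
SPSS workflow it mirrors — treat it as optimistic.
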