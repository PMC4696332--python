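# Methods

This note records the model, the numerical conventions, and the design
choices made where the underlying procedure left them open.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and estimator

A recording is a channels × time matrix in microvolts with a sampling
rate (250 Hz in the reference design) and 10–20 labels.  Preprocessing
is deterministic: common-average re-reference first (subtract the
instantaneous spatial mean; idempotent), then consecutive,
non-overlapping 2-s epochs anchored at sample 0 (trailing partial epoch
dropped), then artifact screening.

**Artifact rejection.**  Expert visual rejection is not reproducible, so
screening is a two-threshold rule: an epoch is dropped when any channel
exceeds 100 µV peak-to-peak or a 50 µV sample-to-sample step (both
configurable).  The rule is a declared automated proxy — it keeps the
epoch bookkeeping (≈130–150 of 150 epochs retained on clean data)
without claiming equivalence to human raters.  Rejected epochs stay in
the container with their mask bit cleared, for audit.

**Spectra.**  One Hann-windowed periodogram per kept epoch, averaged —
Welch's method with the epochs themselves as segments and no overlap
("no phase shift" read as zero segment offset).  Density scaling divides
by fs·Σw², i.e. the window's mean square, so broadband levels are
unbiased; `detrend` is off so the estimator is a pure quadratic form and
amplitude-linearity holds to machine precision.  Two-second epochs give
the 0.5 Hz grid every band computation assumes.  The collapsed spectrum
is the unweighted mean over channels; all anchor detection runs on it
because the channel average suppresses single-electrode peak artifacts
(double or absent alpha peaks).

## Anchors

**IAF** is the maximum-power local peak in the inclusive range 5–14 Hz.
A finite-sample spectrum always carries shallow local maxima, so a
candidate peak must have prominence ≥ 25 % of the maximum power in the
range (`prominence_frac`, configurable).  Ties break toward the higher
frequency.  With no qualifying peak the global maximum in range is used
and the result flagged `no-alpha-peak`; a second qualifying peak ≥ 1 Hz
away within 5 % of the winner's power flags `double-peak` (flagged, not
resolved).  No Gaussian fitting or centre-of-gravity refinement: the
0.5 Hz grid is the stated resolution of the method.

**TF** is the power minimum in [max(4, IAF−6), IAF−0.5] Hz.  The
procedure's source describes only "the minimum power in the alpha
frequency range"; anchoring the window to the IAF keeps it
subject-specific and non-empty, and both bounds are configuration.  Ties
break toward the lower frequency; a minimum at either end flags
`tf-at-boundary`.

## Bands, powers, ratios

Bands: delta [TF−4, TF−2), theta [TF−2, TF), alpha1 [TF, mid),
alpha2 [mid, IAF), alpha3 [IAF, IAF+2), with mid the TF–IAF midpoint.
When both anchors sit on the 0.5 Hz measurement grid the midpoint can
fall halfway between bins and is snapped by rounding half up — a
deterministic tie rule; anchors supplied off-grid (e.g. cohort means
such as 6.9/10.9 Hz) keep the exact midpoint, which reproduces the
canonical printed ranges (2.9–4.9, 4.9–6.9, 6.9–8.9, 8.9–10.9,
10.9–12.9 Hz).

Bin assignment is half-open [lo, hi) throughout, so contiguous bands
partition their union exactly (additivity is asserted as a property
test).  Relative power is the band sum divided by the sum over
[2, 45) Hz; in pipeline use a band reaching below the 2 Hz floor (TF
< 6) is clipped to the normalisation range.  Because the denominator
cancels, the alpha3/alpha2 and theta/gamma ratios are identical whether
computed from absolute or relative powers and invariant under any
positive rescaling of the spectrum (asserted to 1e-12).

Beta1 [IAF+2, IAF+5), beta2 [IAF+5, 30) and gamma [30, 45) are **not**
anchored quantities — they are package configuration defaults, and the
theta/gamma ratio depends on the gamma choice.  This is flagged
prominently because no canonical definition of these edges exists in the
individual-band framework.

Risk groups: fixed cut-offs low < 1.0 ≤ middle < 1.17 ≤ high.  The
printed tertile cut-offs leave a gap between 1.16 and 1.17; it is closed
by assigning [1.0, 1.17) to the middle group, consistent with the
high-risk group's reported range starting at 1.17.  An empirical
cohort-tertile rule (ties to the lower group) is available as an
alternative.

## Cohort statistics

ANOVA without covariates is the classic one-way F; with covariates it is
a linear model (group factor + covariates) with a type-II F for the
group effect — the covariate list is named in the source workflow but
not the sum-of-squares type, and type II is the conventional choice for
unbalanced covariate-adjusted designs.  Levene's test (centre = mean) on
the raw outcome gates the post-hoc family at p < 0.05: Games–Howell
under heterogeneous variances, Bonferroni otherwise; 0.05 is the
conventional reading of a gate whose threshold is not stated.  Missing
values: listwise deletion within each analysis.

The stepwise discriminant analysis is forward entry only (an F-to-enter
is specified, no F-to-remove): at each step the candidate with the
largest Wilks'-lambda partial F enters if partial F ≥ 1.0 and its
tolerance — 1 − R² against already-entered variables, computed on the
pooled within-group SSCP — is ≥ 0.01.  The canonical solution follows on
the selected set (eigenvectors of W⁻¹B scaled to unit pooled
within-group variance), with Bartlett chi-square tests on successive
root subsets, a pooled within-group structure matrix, and nearest
centroid classification in canonical space under equal priors.
Accuracy is resubstitution, matching the workflow it mirrors, and is
therefore optimistic; the mean percent correct is the unweighted mean
over groups.  When no candidate reaches the entry criterion the
function returns an explicit null model (no roots, all cases assigned to
the first group level) rather than raising, so chance-level calibrations
on label-shuffled data are well defined.

## Synthetic data

The EEG generator synthesises stationary Gaussian processes in the
frequency domain, shaped by a closed-form one-sided PSD: a 1/f^a
background (default a = 1.4, 12 µV²/Hz at 1 Hz — a typical eyes-closed
resting slope) plus three Gaussian-profile oscillators of ≈1.5 Hz FWHM:
theta at TF−1.5 Hz, low-alpha at IAF−1.5 Hz and high-alpha at the IAF
(amplitudes in RMS µV).  Each channel mixes a scalp-wide shared
realisation and a channel-local realisation of that process
(`shared_fraction`, default 0.3) times a per-channel gain, plus white
sensor noise (2 µV).  The split matters: a perfectly common source would
be annihilated by the common-average reference.  Both the process PSD
and its post-re-referencing, Hann-smeared Welch expectation are
available in closed form (`analytic_collapsed_psd`,
`expected_welch_psd`); the latter is the oracle recovery tests compare
against, because it is exactly what the estimator converges to.

Presets `low-risk` and `high-risk` fix oscillator amplitudes whose
expected-spectrum alpha3/alpha2 ratios are 0.90 and 1.29, the low- and
high-tertile group means, and were chosen so the theta/alpha trough is
decisive (the nearest competing bin sits ≥ 15 % higher in expectation,
comfortably above Welch bin noise at 150 epochs).  Anchor-recovery
experiments draw IAF on the 8–12 Hz grid with TF co-varying as IAF−3.5
(the ≈4 Hz anchor gap seen in MCI cohorts); a fixed 5 Hz theta
oscillator under an 8 Hz alpha peak would produce a physically
meaningless flat search window.

The cohort generator draws per-outcome-group multivariate normals for
(a3/a2, theta/gamma, age, education, MMSE, hippocampal volumes) with
configurable means/SDs and a positive-semidefinite correlation matrix,
truncated to plausible clinical ranges (MMSE ≤ 30, positive ratios and
volumes).  Defaults reproduce the follow-up design: groups of 42/18/14
with a3/a2 1.14±0.3 / 1.26±0.5 / 1.03±0.7 and the matching demographic
profiles.  Group-wise theta/gamma statistics are not tabulated anywhere;
the defaults (3.6/4.4/4.5 ± ≈1.2) encode the reported direction —
higher in both converter groups — at a magnitude consistent with
theta ≫ gamma relative power in elderly resting EEG.  A `rederive` mode
replaces drawn marker columns by running the full signal pipeline on
per-subject generated recordings whose oscillator amplitudes interpolate
between the presets, so the statistics layer can be exercised on
pipeline-derived rather than directly drawn markers.

**What the generator does not emulate:** non-stationarity and drowsiness
drift, ocular/muscle artifact morphology (only amplitude spikes for
rejection tests), volume-conduction topography beyond a gain map,
non-Gaussian amplitude distributions, and any real relationship between
EEG markers and imaging covariates beyond the specified correlation
matrix.  Passing recovery tests therefore show estimator correctness
under the stated spectral model, not clinical validity on patient data.

## Problem sizes and determinism

Simulation-based tests use fixed seeds end to end and are reproducible
bit for bit.  Sizes were chosen to give stable pass/fail behaviour at
desk scale: 50 subjects × 300 s for anchor recovery, 1000 replicates
for ANOVA type-I calibration, two independent 100-replicate batches for
the discriminant chance level, and 100 cohorts of 500 per group for the
marker power check.

## Known limitations

- Cohort-scale published quantities (group marker means, macroarea
  correlations 0.85/0.91, the 88.3 % discriminant classification, all
  imaging correlations) depend on undeposited patient data and are not
  reproduced; property-based substitutes cover the machinery instead.
- Macroarea memberships for the frontotemporal and parietoccipital
  regions follow 10–20 lobe nomenclature (central electrodes in
  neither) and are configurable; no authoritative membership list
  exists.
- The TF search window is a declared proxy; whether the original
  procedure capped TF below a fixed ceiling is unknown.
- EDF files are read (via MNE) but not written — no EDF export library
  is declared as a dependency; the matrix+sidecar dialect is the
  round-trip format.
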