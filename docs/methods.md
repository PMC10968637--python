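# Methods

## The classification model

A trial is a channels × samples matrix `X` of press-locked EEG, conditioned
by a zero-phase 1–30 Hz Butterworth bandpass (order 4 per pass), common
average reference, baseline correction against the −500..0 ms pre-press
window, and extraction of the 0..500 ms analysis segment with its own mean
removed per trial and channel. Filtering is done on the continuous signal
when one is available, so filter edge transients never sit inside an epoch;
pre-epoched data is filtered trial-wise with reflection padding, an
approximation that is good for epochs much longer than the filter's
impulse response.

**Spatial filtering (DSP).** With class-mean matrices `M_e`, `M_c`, the
between-class scatter is `S_b = (M_e − M_c)(M_e − M_c)ᵀ` and the
within-class scatter `S_w` sums squared deviations of each trial from its
own class mean, normalised by the trial count. The filters are the top
generalized eigenvectors of `(S_b, S_w + γ·tr(S_w)/C·I)`, unit-normalised
in the regularized `S_w` metric, ordered by descending eigenvalue, each
sign-fixed so its largest-magnitude entry is positive (removes the
eigenvector sign ambiguity from serialized models). Shrinkage default
γ = 0.05: ErrP training sets are a few hundred trials against 35 channels,
and the bare `S_w` can be ill-conditioned.

**Pattern matching.** Each trial yields up to three scalar class-contrast
features, positive favouring "error": a Pearson contrast between the
vectorised projected trial and each projected template; a normalised
Frobenius-distance contrast; and a canonical-correlation contrast where
the d projected components are treated as variables observed over time and
the summary is the arithmetic mean of all d canonical correlations (stable
for the small d used here). Canonical correlations are computed by QR
orthonormalisation of the centred time courses and an SVD of the product
of the two bases; directions with no variance contribute ρ = 0. All three
features are exactly invariant to a common positive rescaling of trial and
templates, and all three negate exactly under a class-label swap.

**Decision.** A Fisher linear discriminant on the standardized selected
features: `w = Σ⁻¹(μ_e − μ_c)` with the pooled within-class covariance and
the bias at the midpoint of the projected class means; score > 0 ⇒ error.
Zero-variance features are dropped with a warning.

**Cross-fitted classifier training.** The LDA is trained on out-of-fold
features: the training set is split into 5 stratified folds and each
trial's features are computed with DSP filters and templates fit on the
other folds (`fit_dcpm(cross_fit=5)`). Features computed against templates
that contain the trial itself are optimistically shifted — every trial
correlates with its own class mean, and the chance component of the
template difference separates exactly the trials it was averaged from — so
a resubstitution-trained threshold lands where genuinely unseen trials
never fall. Cross-fitting restores the match between the training-feature
distribution and test conditions at the cost of five extra DSP fits.
`cross_fit=0` gives the plain resubstitution variant.

**Balanced accuracy** is the mean over classes of per-class recall,
`(1/k) Σ TP(i)/S_i`; it equals plain accuracy on balanced data and is the
objective everywhere (error rates around 0.3 make plain accuracy
misleading).

## The configuration search

The improved variant cross-validates over lead subsets, filter dimensions
and feature combinations: stratified 5-fold splits with a recorded seed;
lead subsets are nested top-k prefixes (k ∈ {4, 8, 12, 16, 24, all}) of a
Fisher-separability ranking (per channel, the max over time samples of
`|u₁−u₂|/(s₁+s₂)` across trials), recomputed inside each training fold so
channel selection never sees held-out data (a deliberately leaky variant
exists behind `SearchSpace.leaky_ranking` for comparison); dimensions 1–6
(skipped when larger than k); all 7 nonempty feature subsets. The winner
maximises mean held-out balanced accuracy; ties go to smaller k, then
smaller dimension, then the earlier subset in lexicographic
(corr, dist, cca) order — the simplest template wins. The winning triple
is refit on all training trials.

Evaluation is always within-subject: train and test trials come from the
same recording (`split_epochs`, stratified). The spatial filter and the
subject's noise geometry are calibrated jointly; transferring a template
across subjects is out of scope, and in the synthetic world a different
generator seed *is* a different subject (fresh spatial mixing matrix).

## Screening indices

Per lead, on the conditioned 0–500 ms trials:

- **Pearson contrast** `1 − corr(x_err, x_corr)` between the class-average
  waveforms (0 = identical, 2 = anti-correlated). Class averages rather
  than single trials: trial-pairwise correlation is ill-defined for
  unequal class counts.
- **F-score** per time sample across trials, with the grand mean, class
  means, and class sums of squares over n±−1; aggregated per lead as mean
  and max over time.
- **Fisher separability** per time sample, `|u₁−u₂|/(s₁+s₂)` with *sample
  variances* (ddof = 1, consistent with the F-score denominators) — not
  standard deviations. This choice sets the scale on which the screening
  threshold 0.15 is meaningful, and makes the index scale as 1/c under
  amplitude scaling by c.

Region aggregates (F, C, P, O, CB by 10–20 prefix; CB = CB1/CBZ/CB2) are
the max over member channels. A subject passes screening iff the CB-region
Fisher max ≥ 0.15. Degenerate cases: zero denominator with distinct means
reports +inf; with equal means, 0.

ERN/Pe morphology is read from *baseline-corrected* (not zero-meaned)
class averages: the ERN is the window minimum in 200–400 ms, the Pe the
window maximum in 250–500 ms, latencies in ms post-press. Zero-meaning the
analysis window would subtract each bump's own DC and bias the recovered
amplitude by several tenths of an a.u. Flat traces are flagged rather than
reported as peaks.

## The synthetic generator

The generator emulates what the method assumes about press-locked ErrP
EEG; defaults are the study conditions used throughout the tests.

- 35-channel montage with CB1/CBZ/CB2, 1000 Hz, epochs −500..+500 ms,
  300 trials, error rate 0.3.
- Background noise: per-channel 1/f (α = 1) sources synthesized in the
  frequency domain, normalised to unit variance, spatially mixed by
  `(1−m)·I + m·Q` (Q random orthogonal, rows renormalised), default
  m = 0.5 and sd 1 a.u. The mixing gives the DSP genuine common-mode
  structure to suppress; the mixing matrix is a subject-level trait.
- Error trials add Gaussian-windowed monophasic bumps (width = FWHM:
  80 ms ERN, 120 ms Pe) at their lead groups with small bilateral spread;
  amplitudes and mean latencies are the group statistics listed in the
  README; correct trials are noise only. Per-trial latency jitter is
  Gaussian, sd 15 ms, truncated to keep the bump inside the epoch. The
  printed latency spreads of group data are dominated by between-subject
  variability; 15 ms within-subject jitter keeps the class-average peak
  attenuation under ~10%, so the configured amplitudes are recoverable
  from the average (verified by the peak-recovery test).
- a.u. map 1:1 onto µV; no claim of absolute calibration.
- Everything (labels, noise, jitter, mixing) is drawn from one seeded
  stream; identical seeds give bit-identical output.

**Cohort conditions** (`cohort_base_config`, used by the screening
studies): 450-trial sessions, noise sd 2, mixing 0.25, global component
scale 0.3, cerebellar component scale swept linearly over 0..2 across
subjects, screening computed on the full session and classification on a
60/40 split. These settings were chosen so that both instruments operate
in their sensitive ranges. The Fisher index of a no-signal lead is not
zero: it is the maximum over ~500 time samples of a finite-sample
statistic, and this noise floor *rises* as trial counts shrink or noise
amplitude drops (the index scales as 1/amplitude). At the single-subject
defaults (300 trials, sd 1) the floor sits above 0.15 and screening would
pass everyone; at the cohort conditions it sits safely below, cerebellar
signal spans the threshold, and balanced accuracy is off its ceiling so
between-subject differences in cerebellar expression are measurable.

**Focal conditions** (`focal_config`, used by the improvement study): the
discriminative components confined to FCz + CB1/CBZ/CB2, spatially
independent noise (m = 0), 120 trials, scale 0.5, and conditioning without
the average reference — re-referencing would place −1/35 of the signal on
every channel and defeat the confinement. Short sessions with mostly
signal-free leads are the regime where an all-channel spatial filter
overfits chance covariance structure and data-driven lead screening has
something real to win; at the generator defaults the fixed configuration
is already near ceiling and the search can only match it.

## What the synthetic studies do and do not show

Passing tests demonstrate that the implementation is faithful to its
definitions (formula oracles, eigen residuals, antisymmetries), that the
full pipeline detects a signal with the configured structure and degrades
to chance without it, that configuration search helps exactly where the
fixed configuration is mis-specified, and that the cerebellar screening
logic selects better-performing subjects when cerebellar expression drives
separability *by construction*. They do not show that real ErrP data has
this structure: real noise is non-Gaussian and nonstationary, artifacts
are absent here (out of scope), component topographies are simplified
(no volume conduction model), and the cerebellar dominance of the cohort
is designed in, not discovered. Absolute numbers (accuracies, correlation
sizes, the screening gain) are properties of the synthetic conditions and
should not be compared across worlds — only directions and contracts
carry over.

## Numerical choices and degenerate inputs

- Epoch windows are half-open sample ranges `[round(start·fs),
  round(start·fs)+N)`, `N = round((end−start)·fs)`: identical length for
  every trial.
- Generalized eigenproblems go through `scipy.linalg.eigh(S_b, reg)`;
  eigenvalues are clipped at 0 (tiny negative values are round-off).
- Canonical correlations are clipped into [0, 1]; rank-deficient time
  courses drop to a smaller basis and missing directions count as ρ = 0.
- The pooled feature covariance gets a 1e−8·tr/p ridge so single-trial
  classes and collinear features stay solvable.
- Pearson correlations of zero-variance vectors: features return 0 (a
  flat projection carries no template preference); the screening index
  raises instead, because a flat class average means the input was not
  conditioned.
- Fold assignment, label draws, jitter and noise all come from explicit
  seeds; there is no hidden global-RNG state anywhere.
- BrainVision export stores float32 (the format's float width): round
  trips are exact to ~1e−7 relative, which the tests budget for.

## Known limitations

- Two-class only; the multi-class extension of the template strategy is
  not implemented.
- Channel ranking uses nested top-k prefixes of one ranking, not arbitrary
  subsets; a signal spread across many weakly-informative leads that the
  max-over-time Fisher score ranks poorly could be missed.
- The cross-validated search returns a single winner; no uncertainty on
  the selected configuration is reported.
- Trial-wise bandpass of pre-epoched data tolerates small edge effects;
  prefer the continuous path when markers are available.
- EDF/BrainVision reading covers the standard cases exercised by the
  tests (voltage channels, stimulus markers); exotic channel types rely on
  MNE's behaviour.
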