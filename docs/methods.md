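# Methods

## Data model and preprocessing

The pipeline starts from *cleaned* continuous HbO recordings (channels ×
samples, µM); optical conversion, motion correction and short-channel
regression are upstream concerns. Trials are epoched as 2 s baseline,
12–15 s stimulus, 10 s post-stimulus, with the inclusive-endpoint convention
`n = round(total·fs) + 1` (2+15+10 s at 50 Hz → 1351 samples) and time 0 at
stimulus onset. The post-stimulus period is interpreted as 10 s after
stimulus *offset*, since published HRF time axes for such paradigms extend
well past the stimulus end; the alternative reading (10 s after onset) would
truncate the response and is not used. Each epoch is baseline-corrected by
subtracting the per-channel mean of the half-open baseline window — applied
by default (toggleable) because interpretable µM magnitudes and a
near-zero DC level are assumed downstream. Trials are averaged
arithmetically per (subject, condition). Upsampling to a common rate uses
linear interpolation (endpoints exact); polyphase resampling is available
behind a config switch. Channels are split into hemispheres by an explicit
map (default: first half left, second half right, matching the usual 1–10 /
11–20 numbering).

## Tensor construction

CPD operates on a 4-way nonnegative tensor (time-frame × frequency ×
channel × subject): per channel, a short-time Fourier magnitude spectrogram
with a 10 s Hann window and 75% overlap, frames fully inside the epoch,
positive frequencies only. Magnitude (not power, not complex) is the
minimal nonnegative reduction of the coefficients; the DC bin is dropped
with the negative frequencies since baseline correction already removes
most of it. The window/hop are engineering defaults — long enough to
resolve sub-0.1 Hz hemodynamics within a 24–27 s epoch — and configurable.
Tucker operates on the signed 3-way tensor (time × channel × subject).
Subject-axis order is deterministic (sorted by subject id, then
within-factor level); in mixed designs each subject contributes one slot
per within level, so 36 subjects yield a subject mode of 72.

## Decomposition

**Nonnegative CPD** is fit by HALS: block-coordinate nonnegative least
squares with exact column-wise coordinate minimization, so the squared
error is monotonically nonincreasing (asserted in tests). Multiplicative
updates were rejected for slow convergence. Initialization is uniform
random, scaled so the initial reconstruction has the tensor's norm; dead
columns are reseeded at machine-epsilon scale. Defaults: tol 1e-8 on the
relative objective change, 500 max sweeps. Factor columns are normalized to
unit L2 with the scale collected in per-component weights λ_r — the
convention screening thresholds rely on. The ensemble runs 10 restarts with
per-run seeds derived from the master seed via `SeedSequence`, so the
ensemble is reproducible and each run distinct.

**Orthogonal Tucker** is initialized by truncated HOSVD and refined by
HOOI; the captured core norm is nondecreasing per sweep and factors are
orthonormal to machine precision by construction. The subject mode is never
compressed, so each subject keeps a score for every (temporal, spatial)
component combination.

**Rank selection** fits ranks 1..R_max once each from a fixed audit seed
(distinct from ensemble seeds, so selection does not depend on `n_runs`)
and returns the smallest rank with relative error < 10%, plus the whole
error curve for elbow inspection — the "significant decrease" reading of
the criterion is left to the analyst; the threshold rule is primary.
Selection fits use a reduced iteration cap (200) since only the error level
matters. Tucker rank pairs are scanned with the HOSVD tail-energy bound
`sqrt(Σ discarded σ_t² + Σ discarded σ_c²)/‖Y‖` (an upper bound on the
HOOI error), in the order smallest Rt+Rc, then smallest Rt.

## Screening

Temporal components whose mean absolute value over [onset+2 s, stimulus
offset) falls below 0.01 are baseline-only and excluded. The 0.01 value is
defined on unit-L2-normalized components and is therefore
normalization-dependent — it is configurable for that reason. Spectral
components are excluded when their peak-magnitude frequency exceeds
0.1 Hz (argmax statistic; ties resolve to the lowest frequency; a
spectral-centroid alternative sits behind a flag). Longer paradigms or
adult data may warrant a different cutoff (e.g. 0.5 Hz).

Cross-run consensus links components from different runs whose temporal
*and* spatial vectors correlate at r > 0.5 with p < α (p from the t
transform of r with n−2 df); requiring both is the stricter reading of the
matching criterion, an either-mode flag exists. Clusters are connected
components of this graph (transitive closure) rather than cliques —
simpler, at a documented risk of chaining; clusters spanning fewer than two
runs are never promoted. Member vectors are averaged after unit
normalization (sign is fixed by nonnegativity) and re-normalized;
`occurrence_weight` is the fraction of runs represented. The once-run
Tucker decomposition bypasses consensus; its temporal components still pass
through the temporal exclusion.

Consensus components additionally carry an averaged subject-score vector
(members' subject columns scaled by λ_r, then averaged). The per-run
component ANOVAs are still computed and reported as raw significance
counts, but selection for the profiles uses the consensus-level ANOVA: it
tests the stable, weighted entity the profiles are built from, avoids
counting the same underlying component up to ten times, and keeps results
and components aligned one-to-one.

## Inference

Between-subjects 2×2 ANOVA uses Type III sums of squares (sum-to-zero
contrasts, statsmodels OLS), valid under unbalanced cells; the mixed-model
ANOVA (one within factor) uses the classic univariate partition (pingouin),
the between effect tested against the subject-within-group mean square.
Both are verified against independent hand-computed sums-of-squares oracles
to 1e-8. No multiple-testing correction is applied across components
(α = .05 per test); an optional Benjamini–Hochberg flag exists, off by
default. Degenerate 0/0 F ratios (no effect and no error variance) are
reported as F = 0, p = 1.

Significant components are summed as absolute values — Tucker factors are
signed while the profiles are magnitude-like — weighted by occurrence for
CPD. Tucker combinations are additionally weighted by their magnitude in
the decomposition (the core-fiber norm, equal to the subject-score norm by
isometry): factor columns are unit vectors, so without this a marginally
significant noise combination would contribute to the profiles on equal
footing with the dominant one. The TOI is the within-stimulus argmax of the temporal profile ± 1 s
(the follow-up window half-width), clipped to the stimulus period; ties go
to the earlier peak. A profile whose global maximum is post-stimulus yields
no TOI unless some within-stimulus value reaches 50% of it (configurable).
The ROI is every channel reaching 50% of the spatial-profile maximum; the
prominence fraction and half-width are reported in every output since no
canonical values exist. Bayes-factor follow-ups compute mean HbO over
[TOI start − 1 s, TOI end + 1 s] × ROI per subject/condition and apply JZS
t tests (Cauchy scale 0.707, the convention of common Bayesian-analysis
software; configurable), two-sample for between contrasts and paired by
subject id for within contrasts; the default contrasts are the factor-A
simple effects within each level of B. The implementation is checked to
1e-3 against direct numerical integration of the JZS marginal likelihood.

## Grand-averaging baseline

Mean over the predefined TOI per channel, then mean over the predefined ROI
channels (that order, though the steps commute for complete windows), then
the same 2×2 ANOVA machinery. TOI and ROI must be supplied explicitly in the
config — the method's defining assumption.

## Synthetic data

The generator emulates trial-averaged infant fNIRS sessions: 20 channels
(10 per hemisphere) by default, 12 trials per subject (blocked by within
level in mixed designs), per-sample white Gaussian noise (default 0.3 µM)
plus a slow sinusoidal drift (period 30 s, default 0.1 µM) standing in for
systemic physiology. Effects are unit-peak double-gamma bumps confined to a
ground-truth window and channel set, scaled per design cell. One master
seed; per-subject substreams are keyed `(seed, subject_index)` so cohorts
can grow without reshuffling existing subjects.

It does **not** model realistic optics (partial volume), cardiac or
respiratory spectral peaks, motion artifacts, or spatially correlated
physiological noise. Passing recovery tests therefore demonstrates that the
algorithmic chain identifies effects localized in time and channel against
white-plus-drift backgrounds at realistic SNR — not that it is robust to
every artifact structure of real recordings.

## Problem sizes and numerical choices in the test suite

Validation uses desk-scale conditions: 10 Hz sampling, 2+12+10 s epochs,
10 channels, 20 subjects per cell, planted amplitude 1.5× the noise SD,
fixed modest decomposition ranks (CPD rank 5, Tucker (4, 3)) for the
end-to-end runs, and the automatic rank scan on a dedicated 135×16×10×40
rank-4 benchmark tensor (5% noise, clipped at zero to stay in the
nonnegative class). Type-I calibration uses 200 null datasets with a
compact 2+8+2 s epoch and a rank-(1,1) Tucker score per dataset, keeping
the per-dataset tests independent. The white-noise tensors of real-data
scale are not compressible below 10% error, which is why the end-to-end
configuration fixes ranks rather than scanning: the automatic rule is
exercised where a low-rank ground truth exists.

## Known limitations

- The CPD temporal mode inherits the STFT frame rate, so TOI resolution in
  the CPD branch is the hop size (2.5 s at defaults); the Tucker branch
  keeps full temporal resolution.
- Connected-component consensus can chain distinct-but-overlapping
  components into one cluster.
- The consensus-level ANOVA treats averaged subject scores as the tested
  quantity; per-member counts are reported but not used for selection.
- SNIRF support targets the subset needed for continuous processed HbO
  (one data block, per-channel measurement lists, stim groups); it is not a
  general SNIRF validator.
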