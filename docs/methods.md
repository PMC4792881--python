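# Methods

## Model and procedure

`sleepseg` treats vigilance as a latent 3-state Markov chain (Wake, NREM,
REM) observed through per-epoch EEG/EMG features. The pipeline has four
stages.

**Feature extraction.** Each channel is filtered once over its whole length
with a zero-phase (forward–backward) 3rd-order Butterworth band-pass, then
cut into epochs (default 4 s; a trailing partial epoch is discarded, never
padded). Per epoch: EMG r.m.s. in 80–100 Hz, and two EEG mean-squared power
ratios, delta/theta (0.5–4 over 6–9 Hz) and high/low (9–45 over 0.5–9 Hz).
Zero-phase filtering was chosen because one-pass filtering would smear
state transitions across epoch boundaries by the filter's group delay; the
consequence is that the effective magnitude response is the *squared*
Butterworth response, which the analytic test oracles account for. Each
feature series is smoothed with a trailing 4-epoch (16 s) moving average —
trailing rather than centered because a 4-point window cannot be symmetric
and causality permits online scoring; the first three epochs use the
shorter windows available — and natural-log transformed (log base is an
arbitrary monotone rescale; it affects reported values, not cluster
topology). Smooth-then-log is the default order; log-then-smooth is a
config switch. Denominators and pre-log values are floored at 1e-12
(squared-µV) so silent channels yield finite output. All three features are
log-scaled uniformly.

**Two-stage staging.** k-means (k-means++ seeding, Lloyd iterations, best
of 10 restarts by within-cluster sum of squares, 300-iteration cap) is run
twice in one dimension: on the EMG axis (higher centroid → Wake) and then
on the delta/theta axis of the sleep epochs (higher centroid → NREM). The
1-D two-stage design, rather than a single 3-D clustering, makes the
partition axis-aligned with the physiology and the label mapping
order-driven, hence invariant to monotone axis rescaling. Per-state means
in z-scored 3-D feature space become the centroids for out-of-sample
nearest-centroid scoring (ties resolve Wake → NREM → REM). Standardization
uses the training sample's per-feature mean/sd because EMG power and log
ratios have incommensurate scales.

**Codebook.** A second k-means quantizes the z-scored 3-D space into M
centroids, M ∈ [3, 15]. The selection statistic is the explained-variance
criterion VC = SSB/SST ∈ [0, 1] (the F-statistic-like form that *increases*
as clusters tighten); the smallest M with VC ≥ 0.90 is kept, or M = 15 with
a warning flag when the threshold is unreachable (e.g. a single Gaussian
blob: VC ≈ 0.79 at M = 15). All three features enter the codebook
clustering.

**Discretized-observation HMM.** A[i,j] is the relative frequency of i→j
transitions in the staged training labels; B[i,m] the relative frequency of
symbol m within state i. Every probability row is floored at 1e-6 and
renormalized after counting and after every M-step so that symbols or
transitions unseen in training never make an out-of-sample sequence
impossible. The initial distribution π is the stationary distribution of A
(appropriate for long recordings; an empirical first-state mode is
available) and is re-estimated by EM along with A and B. Baum–Welch uses
scaled (normalized) forward–backward recursions with closed-form M-steps;
convergence when the relative log-likelihood improvement falls below 1e-6
or after 500 iterations (both configurable). Refinement defaults to on but
can be disabled to score with the initial-guess model. Multiple random EM
restarts are deliberately not offered: the staged initial guess is the
method's initializer. Viterbi decoding runs in log space with backtracking;
ties break toward the earliest state in (Wake, NREM, REM) order.

**Metrics.** Bouts are maximal same-state runs; first and last runs count
as full bouts and no merging across brief interruptions is performed. A
state with no bouts reports mean bout duration as NaN, not 0, so plots can
distinguish "absent" from "zero-length". Specificity is one-vs-rest.
Cohort comparisons use scipy's Wilcoxon signed-rank (exact small-sample
distribution where applicable, mid-ranks for ties) and Spearman
correlation; the bout-overcount direction test is an exact two-sided
binomial sign test.

## Synthetic data: what it emulates and what it does not

The generators produce (a) hypnograms from diagonal-dominant Markov chains
— the light-period preset has stationary proportions (0.350, 0.545, 0.105)
for Wake/NREM/REM with mean dwells of roughly 2.5/4/1.3 minutes, the
dark-period preset (0.746, 0.242, 0.012) with REM near 1%, the regime where
REM's conditional distribution is poorly estimated; (b) features from
state-conditioned diagonal Gaussians whose default geometry separates Wake
from sleep by ~6 sd on the EMG axis and NREM from REM by ~10 sd on the
delta/theta axis (separable but overlapping at sd 0.35); and (c) raw
signals with fixed mid-band sinusoids (NREM 2 Hz amp 3, REM 7 Hz amp 2,
Wake 12 Hz amp 1, EEG noise sd 0.5) and state-scaled EMG noise (Wake 2.0,
sleep 0.3) band-limited to 10–100 Hz — fixed frequencies rather than
stochastic narrowband processes, so band-power ratios are analytically
predictable. Diagonal covariances keep the parameter count small while
reproducing the cluster geometry.

What the synthetic data does **not** contain: 1/f EEG background, spindles
and K-complexes, movement artifacts, electrode drift, inter-animal EMG
gain differences, or dwell-time distributions deviating from geometric.
Passing tests therefore demonstrate correctness of the algorithms under
the model's own assumptions, not expected accuracy on real recordings.

Cohort simulation jitters chain off-diagonals and feature means/sds
multiplicatively (default ±5%) per subject. The cohort *evaluation*
harness inflates feature sds by 2.5× — at that noise the per-epoch scorer's
Wake/sleep separation drops to ~2.5 sd and its output flickers, which is
the regime the dynamics comparison is about; the value was fixed once as
the condition defining that regime.

## Numerical choices and problem sizes

- k-means is scikit-learn's Lloyd implementation (k-means++, `n_init=10`,
  fixed `random_state`); determinism per seed throughout, all seeds
  derived from user-supplied integers.
- Scaled forward–backward for EM, log-space for Viterbi: the standard
  stability pairing with exact M-step formulas.
- Probability floor 1e-6: large enough to survive renormalization, small
  enough that the EM log-likelihood trace remains non-decreasing to well
  under 1e-9 on all tested fixtures.
- VC of an all-identical point set is 0 by convention; empty-cluster
  relocation during Lloyd iterations follows scikit-learn.
- Default problem sizes in tests and the acceptance script — 100
  enumeration instances (T ≤ 8), T = 20 000 for transition recovery,
  T = 12 600 (~14 h) for pipeline recovery, 18 subjects × 5400 epochs
  (~6 h) for the cohort — were chosen so each statistic's sampling error is
  comfortably below its assertion margin while the whole suite stays quick
  on a single CPU.

## Known limitations

- Exactly three states; brief arousals and long Wake bouts share one state
  even though they are dynamically distinct (a hierarchical or explicit
  dwell-time model would be needed).
- Dwell times are implicitly geometric.
- Models do not transfer across animals; EMG gain differences shift the
  feature clusters (cross-subject scoring is out of scope).
- EDF support: reading requires `mne`; the built-in writer is minimal
  (16-bit, 1-s records) and intended for synthetic fixtures.
- The `.mat` feature loader maps any `*light*`/`*dark*` N×3 numeric matrix;
  it assumes the stored features are already smoothed and log-scaled.
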