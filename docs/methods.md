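# Methods

This note documents the models, parameter choices and known limitations of
`callrep`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

Given a set of labeled single-caller call clips (one vocalization per file,
a metadata row with caller, community, date and a putative call-type
label), the pipeline asks whether the putative types are acoustically
discriminable, and produces an *updated repertoire* in which
non-discriminable types are merged into the type they are confused with
most. The reference use case is a wild bonobo dataset of 1509 calls / 15
putative types / 53 callers; the package ships that study's published
confusion matrix (`callrep.reference_data`) as a worked example and
regression anchor, including its printed bookkeeping quirks (cells sum to
1506 against a stated 1509; two printed per-class errors differ in the
third decimal from the recomputed values).

## Acoustic features (31 per call)

Calls are band-limited with a 5th-order Butterworth band-pass
(200–4000 Hz, zero-phase forward–backward filtering, > 40 dB stop-band
rejection) — the band where the target calls carry energy and outside of
which rainforest recordings are dominated by insect and handling noise.
Spectrograms use 512-sample Hann windows with 50% overlap at 44.1 kHz
(≈ 86 Hz × 5.8 ms resolution); frames more than 60 dB below the loudest
frame are treated as silence for contour tracking.

The 26 spectral/temporal parameters are the ones bioacoustic toolkits
conventionally extract per call (duration; weighted mean/SD/median/
quartiles/IQR/skewness/kurtosis of the band-limited mean spectrum;
spectral, temporal and joint entropies; spectral flatness; peak frequency;
mean per-frame peak frequency; dominant-frequency mean, min, max, range,
start, end, slope and modulation index; temporal energy quartiles).
Frequencies are reported in kHz, times in seconds; all frequency-valued
features are constrained to the analysis band by construction. The
modulation index is `sum(|Δdominant|)/range`, defined as 0 for a flat
track.

The dominant-frequency contour (per-frame argmax frequency) is linearly
resampled to 20 points so calls of different durations are comparable;
pairwise contour distances use unconstrained dynamic time warping
(symmetric step pattern, |·| local cost) on kHz values *without*
z-normalization — register differences between call types are class
information here, not nuisance. Classical (Torgerson) MDS — double
centering of squared distances, eigendecomposition, top-5 axes scaled by
√eigenvalue — converts the DTW matrix into 5 coordinates per call. Axis
sign indeterminacy is fixed by orienting each axis so its
largest-magnitude coordinate is positive; rank-deficient matrices are
zero-padded with a warning. Contour length (20) and the noise-floor rule
(−60 dB) are package conventions; nothing in the downstream statistics is
sensitive to them at the tested scales.

## Outlier hygiene

For each of the 31 columns independently (MDS coordinates included),
z-scores are computed once from the raw column mean and sample SD
(ddof = 1); values with |z| > 3.29 (the two-sided 0.1% normal point) are
replaced by the raw column median. One pass, no recomputation, no grouping
by type or caller. Zero-variance columns are skipped with a warning. Note
the rule is *not* idempotent in general (replacement shifts the moments);
the tested guarantee is weaker: replacements never leave the observed
range, and exact-median preservation holds when fewer than half the values
of an odd-length column are replaced.

## Weighted random forest and OOB evaluation

The forest is an explicit bagging loop over scikit-learn decision trees:
1000 trees, mtry = ⌊√p⌋ (5 for p = 31) features considered per split,
fully grown. Class imbalance is handled by *weighted bootstrap sampling*:
call weights ∝ inverse class relative frequency (normalized to mean 1) are
used as sampling probabilities for each tree's bootstrap, so rare types
are oversampled rather than merely up-weighted in the loss. An alternative
mode (`weight_mode="fit"`) passes the weights to the tree-fitting loss
instead; it is not the default because the oversampling reading matches
how such analyses are usually run.

Each call's prediction is the majority vote over trees where it was out of
bag; vote ties go to the heavier (rarer) class, then lexicographic label
order — for inverse-frequency weights the *total* weight per class is
equal by construction, so per-call weight is the meaningful tie key. Calls
never out of bag (vanishingly rare at 1000 trees) fall back to the
full-forest vote with a warning. Everything is deterministic given the
config seed.

Overall OOB agreement is tested against chance p₀ = 1/k with an exact
two-tailed binomial test (minimum-likelihood two-sidedness, as in
`scipy.stats.binomtest`); the test accepts an externally stated dataset
size when a published matrix's cells do not quite sum to the stated n.
Variable importance is permutation-based mean decrease in accuracy,
computed per tree on its OOB calls and averaged.

## Plurality resolution

A type is retained iff its row diagonal is the strict row maximum.
Non-retained types are relabelled to their row-maximum column, following
chains transitively to a retained type. Deliberately conservative edge
rules, each logged in the mapping notes: a tie for the row maximum retains
the type; an off-diagonal tie picks the lexicographically smallest target;
a cycle among non-retained types collapses onto the member with the
largest row sum. All decisions come from the single input matrix — there
is no retrain-after-merge loop (the published procedure is single-pass).
Exhaustive testing over all 3×3 count matrices with entries in {0,1,2}
confirms resolution always terminates with a non-empty retained set.

## Synthetic call generator

Each archetype is a parametric call: an f0 trajectory (flat / rise / fall /
arch / sigmoid between `f0_start` and `f0_end`), `n_harmonics` harmonics
with 1/h amplitudes, mixed with band-limited Gaussian noise so the harmonic
energy fraction equals `tonality`; optional raised-cosine amplitude pulsing
(`pulse_rate`, `pulse_depth`); truncated-normal duration (> 0.02 s); 5 ms
raised-cosine fades; peak level `amplitude_db`. Per-caller individuality is
a multiplicative log-normal jitter (σ = 0.08) on f0 and duration shared by
all of a caller's calls; broadband background noise is added at 20 dB SNR.
Output is RIFF PCM mono 16-bit WAV at 44.1 kHz plus a metadata CSV; the
whole dataset is a deterministic function of the spec (including its seed).

The default bank of five well-separated archetypes (tonal arch-contour
hoot, noisy rising scream, low grunt, flat whistle, pulsed laugh) drives
recovery tests; a fifteen-archetype bank named after the bonobo call types,
with per-class sizes equal to the published matrix's row sums (29–284),
provides a realistically small, unbalanced, noisy dataset shape. All
archetype numbers are generator conventions, not measurements.

**Gradedness.** One knob λ ∈ [0, 1] linearly interpolates every
distribution-shaping archetype parameter toward the grand mean (log-scale
for frequencies and durations, linear otherwise; harmonic counts rounded;
pulse depth fades as 1−λ; contour shapes collapse to flat only at λ = 1).
At λ = 0 classes are as defined; at λ = 1 they are statistically
exchangeable, and measured OOB accuracy falls into the binomial band
around 1/k.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: reverberation and distance-dependent filtering,
overlapping callers, non-stationary background (cicada bands), amplitude
clipping, and — most importantly — *asymmetric* label/acoustics mismatch.
The last point matters for the merge rule: with inverse-frequency
weighting equalizing class mass, two labels drawn from the *same*
generator face a symmetric diagonal-vs-twin race (each row's diagonal is
≈ Binomial(n, ½)), so whether the pair merges is close to a coin flip
rather than near-certain; experiments with shifted or mixture "satellite"
classes either become separable (and are correctly retained) or inherit
the same symmetry. Real merges, like the bark→high-hoot folds in the
reference matrix, rest on directional confusion structure that clean
parametric classes do not produce. The merge logic itself is therefore
validated on deterministic matrices (the published table, the didactic
three-type example, exhaustive small matrices), while the end-to-end
duplicate-merge check documents the symmetric behaviour honestly rather
than tuning the generator around it. A related caveat: shared per-caller
jitter induces caller signatures (pseudo-replication), which slightly
inflates OOB accuracy for any class mixture — as it does in real datasets
where callers contribute many calls.

## Problem sizes and numerical choices

End-to-end stochastic checks run at 5 archetypes × 40 calls/class × 10
seeds (test suite) or 3 seeds (acceptance script), 1000 trees — the
package's chosen desk-scale configuration; the reference-matrix analyses
are exact and instantaneous. t-SNE uses perplexity 30 (scikit-learn
defaults otherwise, PCA init, fixed seed) on standardized features and is
purely descriptive. Spectrogram figures use a Hann window with a −30 dB
display floor relative to the loudest pixel and short silent margins.
Confusion matrices round-trip through CSV with labels as header/row names
and a trailing `classification_error` column (3 decimals), matching the
published table layout.
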