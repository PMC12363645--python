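# Methods

## Data model

A peri-event dataset is an ordered set of groups (conditions), each a
T × n matrix: T timepoints of an event-aligned, already-preprocessed
signal for n animals or trials. The package carries no time axis — rows
are addressed by 0-based index and windows are inclusive (start, end) row
ranges — so the caller tracks the sampling rate, including after
downsampling (effective rate = original rate / factor). Data are assumed
complete and rectangular: any blank or non-numeric cell inside the data
rectangle is a validation error rather than a NaN, because every
resampling step below assumes a full matrix. When a workbook's first row
is fully numeric it is treated as data, otherwise as column labels; this
heuristic is deterministic but worth knowing when a header happens to be
numeric. A sheet named `settings` is reserved for output metadata and
skipped on input, which lets every output workbook be re-read as a
dataset.

## Bootstrapped confidence intervals

For a single group, each bootstrap iteration draws n column indices with
replacement and averages the selected whole columns, yielding a resampled
mean waveform; B iterations (default 1000) give a T-long empirical
distribution of means at every timepoint. Resampling whole subjects
rather than individual cells leaves the per-timepoint marginal
distribution unchanged while preserving the temporal coherence of the
resampled waveforms, and it makes the subject the unit of inference,
consistent with the permutation tests.

The raw CI is the pair of symmetric empirical quantiles (linear
interpolation between order statistics) at level α = 1 − confidence.
Percentile intervals from small n are systematically narrow, so the
interval is widened about the bootstrap-distribution mean m:

    low' = m − f (m − q_low),   high' = m + f (q_high − m),
    f = sqrt(n / (n − 1))   (f = 1 when n = 1)

The factor's exact form is a genuinely open choice (candidates include
n/(n−1) and its square root); the square-root form is used here and is
isolated in `adjusted_percentile_ci` so it can be swapped in one place.

A timepoint is significant when its interval strictly excludes 0 — an
endpoint exactly at 0 counts as containing the null, a conservative
tie-break that matters only for degenerate data. Three designs share this
machinery: each group against the baseline null of 0 (data are assumed
pre-normalized so 0 is the null; no re-baselining on a window is done),
between-subjects differences (both groups bootstrapped independently with
the same B, the difference distribution tested; the adjustment uses the
conservative n = min(nA, nB), since no single n is canonical for a
difference of groups of unequal size), and within-subjects differences
(column-wise paired difference matrix bootstrapped; equal column counts
required).

### Calibration in practice

The per-timepoint test is anticonservative at photometry-scale sample
sizes: Monte-Carlo calibration on i.i.d. Gaussian noise with n = 7 and
B = 1000 gives ~0.88 coverage for the raw 95% percentile interval and
~0.90 after the square-root adjustment (no reading of the adjustment
reaches nominal coverage; matching a t-based interval at n = 7 would
require widening by ~35%, far beyond n/(n−1)). The acceptance suite
asserts nominal-level calibration bands and therefore carries two
expected failures documenting this; the false positives the per-timepoint
test admits are exactly what the consecutive threshold exists to remove,
and the same suite shows the family-wise probability of any surviving run
dropping from ~1 to ~0 at k = 5 on pure noise.

## Consecutive threshold

`apply_consecutive_threshold` erases every maximal run of consecutive
significant timepoints shorter than k samples; k ∈ {0, 1} is a no-op.
The operation is idempotent and monotone (larger k never adds flags).
`recommend_consecutive_threshold` converts the binding physical
constraint — sensor kinetics (rise + half-decay seconds), low-pass filter
(1 s / filter Hz), or a user-supplied minimum, whichever is longest — to
samples at the data's sampling rate, rounding half up with a floor of one
sample. At 10 Hz the kinetics of a fast dopamine sensor (0.08 s rise,
0.33 s half-decay) give 4 samples and a 6 Hz low-pass filter gives 2.

## Permutation tests

Each window-level test reduces every subject to its window mean, making
animals/trials the exchangeable unit. The statistic is the absolute
difference of group means (two-sided; the output reports the signed
observed difference alongside the p value). Unpaired designs reshuffle
pooled group labels preserving group sizes; paired designs flip the sign
of each paired difference — the standard exchangeability-preserving
scheme for paired data. p = (#permuted |stat| ≥ observed |stat|) /
n_permutations, deliberately without a +1 correction so that p = 0 is
representable and means "below 1/n_permutations"; users wanting finer
resolution raise n_permutations. Equality is tested with a 1e-12 slack so
rational statistics tie exactly despite floating-point rounding.
`exact_permutation_p` enumerates all label assignments / sign patterns
(up to 10^6 arrangements) and serves as the independent oracle for the
Monte-Carlo path in the tests. The consecutive threshold never enters the
window tests, so with a fixed seed p values are identical across
thresholds.

## Pairwise suite and determinism

`run_pairwise_suite` runs, for every unordered group pair, both window
permutation tests plus the per-timepoint difference map, and for every
group the baseline map, all thresholded, and assembles them with a
settings record that is written verbatim to the results workbook. All
randomness derives from one master seed through `SeedSequence` substreams
spawned in a fixed order (groups first, then per-pair map/baseline-window
/comparison-window), so results are bit-identical for a given seed
regardless of the worker count used for the optional joblib
parallelization. An absent seed falls back to OS entropy.

## Downsampler and time bins

The downsampler partitions rows into consecutive blocks of `factor` and
replaces each with its arithmetic mean. A trailing partial block is
averaged and kept as the final row — dropping it would discard endpoint
data, and nothing in the block-mean definition forces either choice — so
813 rows at factor 10 give 82. Consequences: the grand mean is conserved
exactly only when T is divisible by the factor, and composition
downsample(a)∘downsample(b) = downsample(ab) also requires divisibility.
Time bins are arbitrary inclusive (start, end) row ranges; they may
overlap or leave gaps because the interface collects free-form pairs, and
only bounds are checked.

## Synthetic data generator

`generate_event_dataset` emulates an event-aligned, baseline z-scored
recording: i.i.d. Gaussian noise (sd = noise_sd) per cell plus, from the
event row on, a peak-normalized difference-of-exponentials kernel
(1 − e^(−t/rise)) e^(−t/decay) scaled by group amplitude + a per-subject
Gaussian offset (sd = subject_sd). With `paired=True` the subject offsets
are drawn once and shared across groups, giving the correlated columns a
within-subjects analysis needs. Defaults mirror a conventional peri-event
layout — 3 groups × 7 subjects × 813 rows (−20 s to +60 s at ~10 Hz,
event at row 213 so the worked windows 0–212 / 213–812 apply), unit
noise, amplitudes (0, 1, 3) z-units, 0.08 s rise and 0.5 s decay constants,
subject sd 0.3. The generator deliberately omits 1/f noise, bleaching
drift and motion artifacts; passing tests demonstrate calibration and
power under white noise with exchangeable subjects, not robustness to
those real-data features.

## Problem sizes used in validation

The test and acceptance runs use the generator's default geometry
(813 × 7, 3 groups) with 1000 resamples/permutations for single-dataset
checks, 1000 simulations for scalar calibration quantities (null p
uniformity, CI coverage), and 40 replicate datasets for family-wise-rate
estimates, which bounds the full suite to well under a minute while
keeping binomial error small relative to every asserted band.

## Known limitations

- Per-timepoint CIs are anticonservative at small n (see above); report
  thresholded maps, not raw ones.
- No hierarchical (trials-within-animal) bootstrap, BCa/studentized
  intervals, or cluster-mass permutation correction.
- XLSX serialization carries ~16 significant digits, so the very first
  export of binary doubles can differ in the last bit; workbook-to-
  workbook round trips are exact.
- The cloud-synced-directory failure mode some spreadsheet users hit is
  documented here (use local storage for inputs/outputs) but not detected
  programmatically.
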