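# periboot

Post hoc statistics for peri-event fiber-photometry signals.

Fiber photometry records bulk fluorescence from genetically encoded sensors
(GCaMP, GRAB-DA, ...) in behaving animals. After the usual preprocessing
(isosbestic fitting, ΔF/F, baseline z-scoring — all upstream of this
package), the analysis question is *when*, relative to an event, a signal
differs from baseline or between groups. Summary statistics over
user-chosen time bins (AUC, mean z, peak z) answer this with an
experimenter-chosen window and distributional assumptions; `periboot`
instead provides the resampling-based alternatives:

- **Per-timepoint bootstrapped confidence intervals.** At every timepoint
  the mean across animals/trials is bootstrapped (whole subjects resampled
  with replacement, 1000 resamples by default) and a percentile CI is
  formed, widened by the small-sample narrowness adjustment
  `sqrt(n/(n-1))` about the bootstrap mean. A timepoint is significant
  when the CI excludes the null of 0 — versus baseline for a single group,
  or for a bootstrapped difference of group means (between-subjects) or a
  bootstrapped paired difference (within-subjects, equal *n* required).
  The result is a binary significance map over the peri-event window.
- **Consecutive threshold.** Testing hundreds of timepoints inflates
  family-wise Type-1 error, so runs of consecutive significant points
  shorter than *k* samples are erased. *k* is chosen from sensor kinetics
  (rise + half-decay time), any low-pass filter applied during recording
  (1 s / filter Hz), or a user-defined minimum — take the most
  conservative, converted to samples at the data's sampling rate
  (`recommend_consecutive_threshold`).
- **Window permutation tests.** Each subject is reduced to its mean over
  the baseline or comparison window; the two-sided absolute difference of
  group means is compared against label reshuffles (unpaired) or sign
  flips of paired differences (paired), giving an exact Monte-Carlo
  p value per window per group pair.
- **Utilities:** a block-mean downsampler (every *n*-th point averaged,
  trailing partial block kept) and mean time bins, plus a seeded synthetic
  peri-event generator for testing.

Data travel as multi-sheet XLSX workbooks (one sheet per group, one column
per animal/trial, one row per timepoint; CSV-per-group directories also
work). Outputs follow fixed naming: `<stem>_downsampled_<factor>.xlsx`,
`<stem>_time_bin_means.xlsx`, `<stem>_results.xlsx` — the results workbook
carries pairwise window statistics (p values rendered to three decimals;
`0.000` means p < 0.001), the per-pair and per-group binary significance
maps, and a settings sheet echoing every parameter used.

## Worked example

Three simulated groups of 7 subjects over 813 timepoints (−20 s to +60 s
at ~10 Hz, event at row 213) with response amplitudes 0, 1 and 3 z-units
and a slow-decay transient, analyzed within-subjects over baseline rows
0–212 and comparison rows 213–812:

```python
from periboot import (SyntheticSpec, generate_event_dataset, run_pairwise_suite,
    WindowSpec, BootstrapConfig, PermutationConfig, recommend_consecutive_threshold)

k = recommend_consecutive_threshold(rise_s=0.08, half_decay_s=0.33,
                                    sampling_hz=10.0, low_pass_hz=6.0)
print("recommended consecutive threshold:", k, "samples")

spec = SyntheticSpec(amplitudes=(0.0, 1.0, 3.0), decay_s=8.0, seed=7)
dataset = generate_event_dataset(spec)
bundle = run_pairwise_suite(
    dataset,
    WindowSpec(0, 212, 213, 812),
    BootstrapConfig(confidence_level=0.95, n_resamples=1000,
                    consecutive_threshold=k, design="within", seed=7),
    PermutationConfig(n_permutations=1000, design="within", seed=7),
)
for rec in bundle.pairwise:
    print(f"{rec.pair[0]} vs {rec.pair[1]}: "
          f"baseline dm={rec.baseline.observed_mean_difference:+.3f} p={rec.baseline.p_value:.3f}  "
          f"comparison dm={rec.comparison.observed_mean_difference:+.3f} p={rec.comparison.p_value:.3f}  "
          f"significant timepoints={len(rec.significant_rows)}")
```

prints

```
recommended consecutive threshold: 4 samples
group0 vs group1: baseline dm=-0.033 p=0.365  comparison dm=-0.151 p=0.012  significant timepoints=4
group0 vs group2: baseline dm=-0.076 p=0.097  comparison dm=-0.424 p=0.013  significant timepoints=68
group1 vs group2: baseline dm=-0.043 p=0.046  comparison dm=-0.273 p=0.014  significant timepoints=31
```

The sensor-kinetics rule (0.08 s rise + 0.33 s half-decay = 0.41 s) beats
the 6 Hz low-pass rule (1/6 s), so the threshold is 4 samples at 10 Hz.
Baseline windows show no reliable differences; comparison windows separate
all pairs by permutation test, and the per-timepoint maps grade with
effect size: the largest amplitude contrast (group0 vs group2) keeps 68
significant timepoints after thresholding. `write_results(bundle, out_dir)`
writes the four-sheet workbook.

The same analysis runs from the shell:

```sh
periboot --analysis within --input mydata.xlsx \
    --confidence 0.95 --resamples 1000 --permutations 1000 --threshold 4 \
    --baseline 0 212 --comparison 213 812 --seed 7
```

or interactively via the 4-option menu (`periboot` with no flags:
1 between-groups, 2 within-groups, 3 downsampler, 4 time bins).

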