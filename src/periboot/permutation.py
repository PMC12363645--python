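"""Window-level permutation tests and the pairwise analysis suite.

A permutation test asks whether two groups' signals over a whole window
(the pre-event baseline or the post-event comparison period) could have
come from the same distribution.  Each animal/trial is first reduced to its
window mean, making the subject the exchangeable unit; the two-sided
statistic is the absolute difference of group means of those subject
means.  Unpaired (between) designs shuffle group labels over the pooled
subjects; paired (within) designs flip the signs of per-pair differences.
The Monte-Carlo p value is the fraction of permuted statistics at least as
extreme as the observed one; small enumerable problems can instead be
solved exactly with :func:`exact_permutation_p`.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .dataio import validate_equal_columns
from .model import (
    BootstrapConfig,
    CapabilityError,
    DesignError,
    PairwiseRecord,
    PeriEventDataset,
    PermutationConfig,
    PermutationResult,
    ResultsBundle,
    SettingsRecord,
    SignificanceMap,
    ValidationError,
    WindowSpec,
)
from .resampling import (
    apply_consecutive_threshold,
    baseline_significance,
    between_group_difference,
    within_group_difference,
)

__all__ = [
    "window_subject_means",
    "permutation_test",
    "exact_permutation_p",
    "run_pairwise_suite",
]

_EXACT_LIMIT = 10**6
# absolute-comparison slack so rational statistics tie exactly despite fp error
_TIE_EPS = 1e-12


def window_subject_means(values: np.ndarray, start: int, end: int) -> np.ndarray:
    """Mean of rows start..end (0-based inclusive) for each column."""
    values = np.asarray(values, dtype=float)
    T = values.shape[0]
    if start < 0 or end < start or end >= T:
        raise ValidationError(
            f"window ({start}, {end}) invalid: numbers must be non-negative "
            "and the data to be analyzed should be equal to or less than the "
            f"maximum number of rows (max row index {T - 1})"
        )
    return values[start : end + 1].mean(axis=0)


def _perm_stats_between(
    a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    pooled = np.concatenate([a, b])
    na = a.size
    # one random label assignment per row, sizes preserved
    order = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
    shuffled = pooled[order]
    return np.abs(shuffled[:, :na].mean(axis=1) - shuffled[:, na:].mean(axis=1))


def _perm_stats_within(
    d: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    signs = rng.integers(0, 2, size=(n_perm, d.size)) * 2 - 1
    return np.abs((signs * d).mean(axis=1))


def permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    cfg: PermutationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided Monte-Carlo permutation test on per-subject window means.

    Returns ``(observed_mean_difference, p_value)`` where the observed
    difference is mean(a) - mean(b) (signed) and the p value is the
    fraction of ``cfg.n_permutations`` random relabelings (between design)
    or sign flips of the paired differences (within design) whose absolute
    statistic reaches the observed absolute difference.  The denominator is
    exactly n_permutations, so p = 0 means "< 1/n_permutations".
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size < 1 or b.size < 1:
        raise ValueError("both groups need at least one subject")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    observed = a.mean() - b.mean()
    if cfg.design == "within":
        if a.size != b.size:
            raise DesignError(
                "within-subjects permutation test: the same number of "
                "animals/trials in each group is needed"
            )
        stats = _perm_stats_within(a - b, cfg.n_permutations, rng)
    else:
        stats = _perm_stats_between(a, b, cfg.n_permutations, rng)
    p = float(np.count_nonzero(stats >= abs(observed) - _TIE_EPS)) / cfg.n_permutations
    return float(observed), p


def exact_permutation_p(a: np.ndarray, b: np.ndarray, design: str) -> float:
    """Exact two-sided permutation p by complete enumeration.

    Enumerates every equal-size label assignment (between design) or every
    sign pattern of the paired differences (within design).  Intended as an
    independent reference for small groups; refuses enumerations beyond
    10^6 arrangements.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    observed = abs(a.mean() - b.mean())
    if design == "within":
        if a.size != b.size:
            raise DesignError("within design requires paired groups of equal size")
        n = a.size
        if 2**n > _EXACT_LIMIT:
            raise CapabilityError(
                f"2^{n} sign patterns exceed the enumeration limit; "
                "use the Monte-Carlo permutation_test"
            )
        d = a - b
        bits = (np.arange(2**n)[:, None] >> np.arange(n)) & 1
        stats = np.abs(((bits * 2 - 1) * d).mean(axis=1))
    elif design == "between":
        pooled = np.concatenate([a, b])
        na, total = a.size, a.size + b.size
        from math import comb

        if comb(total, na) > _EXACT_LIMIT:
            raise CapabilityError(
                f"C({total},{na}) assignments exceed the enumeration limit; "
                "use the Monte-Carlo permutation_test"
            )
        stats_list = []
        idx_all = set(range(total))
        for chosen in combinations(range(total), na):
            rest = list(idx_all - set(chosen))
            stats_list.append(
                abs(pooled[list(chosen)].mean() - pooled[rest].mean())
            )
        stats = np.asarray(stats_list)
    else:
        raise ValueError(f"design must be 'between' or 'within', got {design!r}")
    return float(np.count_nonzero(stats >= observed - _TIE_EPS)) / stats.size


def _pair_task(
    group_a,
    group_b,
    windows: WindowSpec,
    boot_cfg: BootstrapConfig,
    perm_cfg: PermutationConfig,
    seeds: tuple[np.random.SeedSequence, np.random.SeedSequence, np.random.SeedSequence],
) -> PairwiseRecord:
    map_seed, base_seed, comp_seed = seeds
    if boot_cfg.design == "within":
        ci, sig = within_group_difference(
            group_a, group_b, boot_cfg, np.random.default_rng(map_seed)
        )
    else:
        ci, sig = between_group_difference(
            group_a, group_b, boot_cfg, np.random.default_rng(map_seed)
        )
    sig = apply_consecutive_threshold(sig, boot_cfg.consecutive_threshold)
    results = {}
    for window, (start, end), seed in (
        ("baseline", (windows.baseline_start, windows.baseline_end), base_seed),
        ("comparison", (windows.comparison_start, windows.comparison_end), comp_seed),
    ):
        ma = window_subject_means(group_a.values, start, end)
        mb = window_subject_means(group_b.values, start, end)
        obs, p = permutation_test(ma, mb, perm_cfg, np.random.default_rng(seed))
        results[window] = PermutationResult(
            pair=(group_a.name, group_b.name),
            window=window,  # type: ignore[arg-type]
            observed_mean_difference=obs,
            p_value=p,
        )
    return PairwiseRecord(
        pair=(group_a.name, group_b.name),
        baseline=results["baseline"],
        comparison=results["comparison"],
        map=sig,
        ci=ci,
    )


def run_pairwise_suite(
    dataset: PeriEventDataset,
    windows: WindowSpec,
    boot_cfg: BootstrapConfig,
    perm_cfg: PermutationConfig,
    n_workers: int = 1,
) -> ResultsBundle:
    """Full analysis of every unordered group pair plus per-group baselines.

    For each pair: permutation tests on the baseline and comparison windows
    and a per-timepoint difference significance map (between- or
    within-subjects per the config) with the consecutive threshold applied.
    For each group: a significance-from-baseline map, also thresholded.

    Reproducibility: all randomness derives from ``boot_cfg.seed`` through
    independent per-task substreams spawned in a fixed order, so results
    are bit-identical for a given seed regardless of ``n_workers``.
    """
    windows.validate(dataset.n_timepoints)
    if boot_cfg.design == "within" or perm_cfg.design == "within":
        validate_equal_columns(dataset)

    master = np.random.SeedSequence(boot_cfg.seed)
    pairs = dataset.pairs()
    children = master.spawn(len(dataset.groups) + 3 * len(pairs))
    group_seeds = children[: len(dataset.groups)]
    pair_seeds = children[len(dataset.groups):]

    baseline_maps: dict[str, SignificanceMap] = {}
    baseline_cis = {}
    for group, seed in zip(dataset.groups, group_seeds):
        ci, sig = baseline_significance(group, boot_cfg, np.random.default_rng(seed))
        baseline_maps[group.name] = apply_consecutive_threshold(
            sig, boot_cfg.consecutive_threshold
        )
        baseline_cis[group.name] = ci

    tasks = [
        (ga, gb, windows, boot_cfg, perm_cfg, tuple(pair_seeds[3 * i : 3 * i + 3]))
        for i, (ga, gb) in enumerate(pairs)
    ]
    if n_workers > 1 and len(tasks) > 1:
        from joblib import Parallel, delayed

        records = Parallel(n_jobs=n_workers)(
            delayed(_pair_task)(*task) for task in tasks
        )
    else:
        records = [_pair_task(*task) for task in tasks]

    settings = SettingsRecord(
        confidence_level=boot_cfg.confidence_level,
        n_resamples=boot_cfg.n_resamples,
        n_permutations=perm_cfg.n_permutations,
        consecutive_threshold=boot_cfg.consecutive_threshold,
        design=boot_cfg.design,
        baseline_start=windows.baseline_start,
        baseline_end=windows.baseline_end,
        comparison_start=windows.comparison_start,
        comparison_end=windows.comparison_end,
        seed=boot_cfg.seed,
        input_path=dataset.source_path,
    )
    return ResultsBundle(
        pairwise=tuple(records),
        baseline_maps=baseline_maps,
        baseline_cis=baseline_cis,
        settings=settings,
    )
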