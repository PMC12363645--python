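"""Per-timepoint bootstrapped confidence intervals and significance maps.

Statistical model
-----------------
The subject (animal or trial), not the individual sample, is the unit of
resampling: each bootstrap iteration draws ``n`` whole columns with
replacement and averages them, so one iteration yields an entire resampled
mean waveform.  Per-timepoint marginals are identical to cell-wise
resampling, but temporal coherence of the resampled waveforms is preserved
and the computation vectorizes over all timepoints at once.

Confidence intervals come from empirical percentiles of the bootstrap
distribution, widened about the bootstrap mean by ``sqrt(n / (n - 1))`` to
counter the narrowness bias of small-sample percentile intervals.  A
timepoint is flagged significant when its interval strictly excludes the
null of 0; runs of flags shorter than the consecutive threshold are then
erased to control family-wise error across the many per-timepoint tests.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (
    BootstrapConfig,
    CIBand,
    DesignError,
    GroupMatrix,
    SignificanceMap,
)

__all__ = [
    "bootstrap_mean_samples",
    "adjusted_percentile_ci",
    "baseline_significance",
    "between_group_difference",
    "within_group_difference",
    "apply_consecutive_threshold",
    "recommend_consecutive_threshold",
    "significant_rows",
]


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def bootstrap_mean_samples(
    matrix: np.ndarray,
    n_resamples: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Bootstrap the column-mean waveform of a T x n matrix.

    Each of the ``n_resamples`` iterations draws n column indices with
    replacement once and averages the selected whole columns across every
    timepoint.

    Returns
    -------
    ndarray, shape (n_resamples, T)
        One resampled mean trace per row.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim == 1:
        matrix = matrix[:, None]
    if matrix.size == 0:
        raise ValueError("cannot bootstrap an empty matrix")
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    rng = _as_rng(rng)
    T, n = matrix.shape
    idx = rng.integers(0, n, size=(n_resamples, n))
    # (T, R, n) -> mean over the drawn columns -> (T, R) -> (R, T)
    return matrix[:, idx].mean(axis=2).T


def adjusted_percentile_ci(
    samples: np.ndarray,
    confidence_level: float,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile CI with the small-sample narrowness adjustment.

    Raw bounds are the symmetric empirical quantiles (linear interpolation)
    of the bootstrap distribution; they are then widened about the bootstrap
    mean ``m`` by ``f = sqrt(n / (n - 1))``:

        low' = m - f * (m - q_low),  high' = m + f * (q_high - m)

    ``n`` is the number of subjects the bootstrap resampled, not the number
    of resamples.  For n = 1 the factor is defined as 1 (degenerate case).

    Accepts a 1-D vector of bootstrap estimates (returns two scalars as
    0-d arrays) or an (R, T) matrix (returns length-T bound vectors,
    quantiles taken along axis 0).
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValueError(f"confidence_level must be in (0, 1), got {confidence_level}")
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty bootstrap sample")
    alpha = 1.0 - confidence_level
    q_low, q_high = np.quantile(
        samples, [alpha / 2.0, 1.0 - alpha / 2.0], axis=0, method="linear"
    )
    m = samples.mean(axis=0)
    f = 1.0 if n == 1 else math.sqrt(n / (n - 1))
    return m - f * (m - q_low), m + f * (q_high - m)


def _ci_and_map(
    boot: np.ndarray, confidence_level: float, n: int
) -> tuple[CIBand, SignificanceMap]:
    low, high = adjusted_percentile_ci(boot, confidence_level, n)
    # strict exclusion of the null: an endpoint exactly at 0 is not significant
    flags = ((low > 0.0) | (high < 0.0)).astype(np.int8)
    return CIBand(low, high, boot.mean(axis=0)), SignificanceMap(flags)


def baseline_significance(
    group: GroupMatrix,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CIBand, SignificanceMap]:
    """Per-timepoint CI of one group's mean versus the null of 0.

    The data are assumed already normalized (e.g. baseline z-scored) so that
    0 is the baseline null; no re-centering on a baseline window is done
    here.  The consecutive threshold is deliberately NOT applied — use
    :func:`apply_consecutive_threshold` on the returned map.
    """
    rng = _as_rng(cfg.seed if rng is None else rng)
    boot = bootstrap_mean_samples(group.values, cfg.n_resamples, rng)
    return _ci_and_map(boot, cfg.confidence_level, group.n_subjects)


def between_group_difference(
    group_a: GroupMatrix,
    group_b: GroupMatrix,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CIBand, SignificanceMap]:
    """Bootstrapped difference of independently resampled group means.

    Column counts may differ between the groups; the narrowness adjustment
    uses the conservative n = min(nA, nB).
    """
    if group_a.n_timepoints != group_b.n_timepoints:
        raise ValueError(
            f"groups {group_a.name!r} and {group_b.name!r} have different "
            "numbers of timepoints"
        )
    rng = _as_rng(cfg.seed if rng is None else rng)
    boot_a = bootstrap_mean_samples(group_a.values, cfg.n_resamples, rng)
    boot_b = bootstrap_mean_samples(group_b.values, cfg.n_resamples, rng)
    n = min(group_a.n_subjects, group_b.n_subjects)
    return _ci_and_map(boot_a - boot_b, cfg.confidence_level, n)


def within_group_difference(
    group_a: GroupMatrix,
    group_b: GroupMatrix,
    cfg: BootstrapConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CIBand, SignificanceMap]:
    """Bootstrapped mean of paired per-subject differences (A - B).

    Column j of A is paired with column j of B, so both groups must carry
    the same number of animals/trials.
    """
    if group_a.n_subjects != group_b.n_subjects:
        raise DesignError(
            f"within-subjects comparison of {group_a.name!r} "
            f"({group_a.n_subjects} columns) and {group_b.name!r} "
            f"({group_b.n_subjects} columns): the same number of "
            "animals/trials in each group is needed; with unequal counts it "
            "is appropriate to run the between-groups analysis"
        )
    if group_a.n_timepoints != group_b.n_timepoints:
        raise ValueError(
            f"groups {group_a.name!r} and {group_b.name!r} have different "
            "numbers of timepoints"
        )
    rng = _as_rng(cfg.seed if rng is None else rng)
    diff = group_a.values - group_b.values
    boot = bootstrap_mean_samples(diff, cfg.n_resamples, rng)
    return _ci_and_map(boot, cfg.confidence_level, group_a.n_subjects)


def apply_consecutive_threshold(
    sig_map: SignificanceMap | np.ndarray, k: int
) -> SignificanceMap:
    """Erase runs of consecutive significant points shorter than ``k``.

    k = 0 and k = 1 both mean no filtering (any run of length >= 1 stands).
    """
    if k < 0:
        raise ValueError("consecutive threshold must be >= 0")
    flags = sig_map.flags if isinstance(sig_map, SignificanceMap) else np.asarray(sig_map)
    flags = flags.astype(np.int8).copy()
    if k <= 1 or flags.size == 0:
        return SignificanceMap(flags)
    padded = np.concatenate(([0], flags, [0]))
    edges = np.diff(padded)
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)  # exclusive
    for s, e in zip(starts, ends):
        if e - s < k:
            flags[s:e] = 0
    return SignificanceMap(flags)


def recommend_consecutive_threshold(
    rise_s: float,
    half_decay_s: float,
    sampling_hz: float,
    low_pass_hz: float | None = None,
    user_min_s: float | None = None,
) -> int:
    """Recommend a consecutive threshold (in samples) for a sensor/recording.

    The shortest physiologically meaningful deviation is bounded below by
    the sensor kinetics (rise + half-decay time) and by any low-pass filter
    applied during recording (1 s / filter Hz).  The most conservative
    (longest) of these durations — optionally including a user-supplied
    minimum such as a behavioral-classification time — is converted to
    samples at the data's sampling rate, rounding half up, with a floor of
    one sample.
    """
    if sampling_hz <= 0:
        raise ValueError("sampling_hz must be positive")
    if rise_s < 0 or half_decay_s < 0:
        raise ValueError("durations must be non-negative")
    constraints = [rise_s + half_decay_s]
    if low_pass_hz is not None:
        if low_pass_hz <= 0:
            raise ValueError("low_pass_hz must be positive")
        constraints.append(1.0 / low_pass_hz)
    if user_min_s is not None:
        if user_min_s < 0:
            raise ValueError("user_min_s must be non-negative")
        constraints.append(user_min_s)
    duration_s = max(constraints)
    samples = math.floor(duration_s * sampling_hz + 0.5)  # round half up
    return max(1, samples)


def significant_rows(sig_map: SignificanceMap | np.ndarray) -> list[int]:
    """0-based row indices flagged significant, ascending."""
    flags = sig_map.flags if isinstance(sig_map, SignificanceMap) else np.asarray(sig_map)
    return [int(i) for i in np.flatnonzero(flags)]
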