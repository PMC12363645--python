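"""Core data model for peri-event group datasets and analysis results.

The in-memory layout mirrors the workbook layout used in the field: one
group (condition) per sheet, one column per animal or trial, one row per
peri-event timepoint of an already-preprocessed signal (typically a
baseline z-scored dF/F trace).  Rows are addressed by 0-based index; the
package carries no explicit time axis, so callers track the effective
sampling rate themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Literal, Sequence

import numpy as np

Design = Literal["between", "within"]


class ValidationError(ValueError):
    """Input data violates the structural contract (non-numeric cells,
    empty files, ragged sheets...)."""


class DesignError(ValidationError):
    """The requested analysis design is incompatible with the data
    (e.g. within-subjects comparison of groups with unequal column counts)."""


class CapabilityError(ValueError):
    """The exact computation requested is too large; use the Monte-Carlo
    routine instead."""


@dataclass(frozen=True)
class GroupMatrix:
    """One group/condition: a timepoints x subjects matrix of finite values.

    Parameters
    ----------
    name : str
        Group label (the sheet name in workbook form).
    values : ndarray, shape (T, n)
        Rows are peri-event timepoints, columns are animals/trials.
    column_labels : tuple of str
        One label per column; defaults to "0", "1", ... if omitted.
    """

    name: str
    values: np.ndarray
    column_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValidationError(
                f"group {self.name!r}: expected a 2-D matrix with at least one "
                f"row and one column, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValidationError(
                f"group {self.name!r}: non-finite values present. "
                "Non-numeric data found in Excel sheets or input file is empty."
            )
        object.__setattr__(self, "values", arr)
        labels = tuple(self.column_labels) or tuple(
            str(i) for i in range(arr.shape[1])
        )
        if len(labels) != arr.shape[1]:
            raise ValidationError(
                f"group {self.name!r}: {len(labels)} column labels for "
                f"{arr.shape[1]} columns"
            )
        object.__setattr__(self, "column_labels", labels)

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class PeriEventDataset:
    """Ordered groups of timepoint x subject matrices sharing one time axis."""

    groups: tuple[GroupMatrix, ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        if not groups:
            raise ValidationError("dataset has no groups. "
                                  "Non-numeric data found in Excel sheets or "
                                  "input file is empty.")
        names = [g.name for g in groups]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate group names: {names}")
        rows = {g.name: g.n_timepoints for g in groups}
        if len(set(rows.values())) != 1:
            raise ValidationError(
                "groups have unequal numbers of rows (timepoints): "
                + ", ".join(f"{k}={v}" for k, v in rows.items())
            )
        object.__setattr__(self, "groups", groups)

    @property
    def n_timepoints(self) -> int:
        return self.groups[0].n_timepoints

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    def __iter__(self) -> Iterator[GroupMatrix]:
        return iter(self.groups)

    def __getitem__(self, name: str) -> GroupMatrix:
        for g in self.groups:
            if g.name == name:
                return g
        raise KeyError(name)

    def pairs(self) -> list[tuple[GroupMatrix, GroupMatrix]]:
        """All unordered group pairs in sheet order (AB, AC, BC, ...)."""
        return list(combinations(self.groups, 2))


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and comparison periods as 0-based inclusive row ranges."""

    baseline_start: int
    baseline_end: int
    comparison_start: int
    comparison_end: int

    def validate(self, n_timepoints: int) -> None:
        for label, start, end in (
            ("baseline", self.baseline_start, self.baseline_end),
            ("comparison", self.comparison_start, self.comparison_end),
        ):
            if start < 0 or end < start or end >= n_timepoints:
                raise ValidationError(
                    f"{label} window ({start}, {end}) invalid: numbers must be "
                    "non-negative and the data to be analyzed should be equal "
                    "to or less than the maximum number of rows "
                    f"(max row index {n_timepoints - 1})"
                )


@dataclass(frozen=True)
class TimeBinSpec:
    """User-defined mean time bins as 0-based inclusive (start, end) rows.

    Bins need not be contiguous and may overlap; each bin only has to lie
    inside the data.
    """

    bins: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        bins = tuple((int(s), int(e)) for s, e in self.bins)
        if not bins:
            raise ValidationError("at least one time bin is required")
        object.__setattr__(self, "bins", bins)

    def validate(self, n_timepoints: int) -> None:
        for start, end in self.bins:
            if start < 0 or end < start or end >= n_timepoints:
                raise ValidationError(
                    f"time bin ({start}, {end}) invalid: numbers must be "
                    "non-negative and the data to be analyzed should be equal "
                    "to or less than the maximum number of rows "
                    f"(max row index {n_timepoints - 1})"
                )


@dataclass(frozen=True)
class BootstrapConfig:
    """Parameters for per-timepoint bootstrapped confidence intervals.

    confidence_level is a proportion (0.95 or 0.99 are the conventional
    choices); n_resamples defaults to 1000; consecutive_threshold is in
    samples (0 or 1 mean no run-length filtering); design selects the
    between- or within-subjects comparison; seed makes runs reproducible.
    """

    confidence_level: float = 0.95
    n_resamples: int = 1000
    consecutive_threshold: int = 0
    design: Design = "between"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.confidence_level < 1.0:
            raise ValueError(
                f"confidence_level must be in (0, 1), got {self.confidence_level}"
            )
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if self.consecutive_threshold < 0:
            raise ValueError("consecutive_threshold must be >= 0")
        if self.design not in ("between", "within"):
            raise ValueError(f"design must be 'between' or 'within', got {self.design!r}")


@dataclass(frozen=True)
class PermutationConfig:
    """Parameters for window-level permutation tests."""

    n_permutations: int = 1000
    design: Design = "between"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.design not in ("between", "within"):
            raise ValueError(f"design must be 'between' or 'within', got {self.design!r}")


@dataclass(frozen=True)
class CIBand:
    """Per-timepoint confidence band from a bootstrap distribution."""

    lower: np.ndarray
    upper: np.ndarray
    point_estimate: np.ndarray

    def __post_init__(self) -> None:
        lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        point = np.atleast_1d(np.asarray(self.point_estimate, dtype=float))
        if not (lower.shape == upper.shape == point.shape):
            raise ValueError("CI band vectors must share one length")
        if np.any(lower > upper + 1e-12):
            raise ValueError("CI lower bound exceeds upper bound")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        object.__setattr__(self, "point_estimate", point)

    def __len__(self) -> int:
        return self.lower.shape[0]


@dataclass(frozen=True)
class SignificanceMap:
    """Binary per-timepoint significance: 1 marks significance, 0 none."""

    flags: np.ndarray

    def __post_init__(self) -> None:
        flags = np.atleast_1d(np.asarray(self.flags))
        if not np.isin(flags, (0, 1)).all():
            raise ValueError("significance flags must be 0 or 1")
        object.__setattr__(self, "flags", flags.astype(np.int8))

    def __len__(self) -> int:
        return self.flags.shape[0]


@dataclass(frozen=True)
class PermutationResult:
    """One window-level permutation test for one group pair."""

    pair: tuple[str, str]
    window: Literal["baseline", "comparison"]
    observed_mean_difference: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class SettingsRecord:
    """Echo of every parameter a run actually used; written verbatim to the
    settings sheet of the results workbook."""

    confidence_level: float
    n_resamples: int
    n_permutations: int
    consecutive_threshold: int
    design: Design
    baseline_start: int
    baseline_end: int
    comparison_start: int
    comparison_end: int
    seed: int | None
    input_path: str

    def to_rows(self) -> list[tuple[str, str]]:
        return [
            ("confidence_level", repr(self.confidence_level)),
            ("n_resamples", str(self.n_resamples)),
            ("n_permutations", str(self.n_permutations)),
            ("consecutive_threshold", str(self.consecutive_threshold)),
            ("design", self.design),
            ("baseline_start", str(self.baseline_start)),
            ("baseline_end", str(self.baseline_end)),
            ("comparison_start", str(self.comparison_start)),
            ("comparison_end", str(self.comparison_end)),
            ("seed", "" if self.seed is None else str(self.seed)),
            ("input_path", self.input_path),
        ]


@dataclass(frozen=True)
class PairwiseRecord:
    """Window statistics plus the thresholded significance map for one pair."""

    pair: tuple[str, str]
    baseline: PermutationResult
    comparison: PermutationResult
    map: SignificanceMap
    ci: CIBand

    @property
    def significant_rows(self) -> list[int]:
        return [int(i) for i in np.flatnonzero(self.map.flags)]


@dataclass(frozen=True)
class ResultsBundle:
    """Everything the results workbook contains for one analysis run."""

    pairwise: tuple[PairwiseRecord, ...]
    baseline_maps: dict[str, SignificanceMap] = field(default_factory=dict)
    baseline_cis: dict[str, CIBand] = field(default_factory=dict)
    settings: SettingsRecord | None = None

    def __post_init__(self) -> None:
        lengths = {len(r.map) for r in self.pairwise} | {
            len(m) for m in self.baseline_maps.values()
        }
        if len(lengths) > 1:
            raise ValueError(f"significance maps of mixed lengths: {lengths}")
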