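"""Block-mean downsampling and user-defined mean time bins."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import GroupMatrix, PeriEventDataset, TimeBinSpec

__all__ = ["downsample", "time_bin_means", "TimeBinTable"]


def downsample(dataset: PeriEventDataset, factor: int) -> PeriEventDataset:
    """Block-average every ``factor`` consecutive rows of every column.

    Rows are partitioned into consecutive non-overlapping blocks of
    ``factor``; each output row is the arithmetic mean of its block.  A
    trailing partial block (fewer than ``factor`` rows) is averaged and
    kept as the final row, so the output has ceil(T / factor) rows.  Group
    and column structure is unchanged, and no time axis is renumbered:
    callers track the effective sampling rate (original rate / factor).
    """
    if not float(factor).is_integer() or int(factor) < 1:
        raise ValueError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    T = dataset.n_timepoints
    if factor > T:
        raise ValueError(
            f"downsample factor {factor} exceeds the number of rows ({T})"
        )
    if factor == 1:
        return dataset
    starts = np.arange(0, T, factor)
    sizes = np.minimum(factor, T - starts).astype(float)
    groups = []
    for g in dataset.groups:
        sums = np.add.reduceat(g.values, starts, axis=0)
        groups.append(
            GroupMatrix(g.name, sums / sizes[:, None], g.column_labels)
        )
    return PeriEventDataset(tuple(groups), source_path=dataset.source_path)


@dataclass(frozen=True)
class TimeBinTable:
    """Per-group bin-mean tables: rows are bins, columns are animals/trials."""

    per_group: dict[str, pd.DataFrame]
    bins: TimeBinSpec
    source_path: str = ""


def time_bin_means(dataset: PeriEventDataset, bins: TimeBinSpec) -> TimeBinTable:
    """Mean of each column over each (start, end) inclusive row bin.

    Bins are evaluated in the order given; they may overlap or leave gaps.
    """
    bins.validate(dataset.n_timepoints)
    per_group = {}
    for g in dataset.groups:
        rows = [
            g.values[start : end + 1].mean(axis=0) for start, end in bins.bins
        ]
        per_group[g.name] = pd.DataFrame(
            rows,
            index=[f"bin {i}" for i in range(len(bins.bins))],
            columns=list(g.column_labels),
        )
    return TimeBinTable(per_group=per_group, bins=bins, source_path=dataset.source_path)
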