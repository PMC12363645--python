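"""Workbook input/output for the group-per-sheet data model.

Input is an XLSX workbook where each sheet is one group/condition, each
column one animal or trial and each row one peri-event timepoint, or a
directory of per-group CSV files (filename stem = group name).  All
outputs are XLSX with fixed naming contracts derived from the input stem:

    <stem>_downsampled_<factor>.xlsx
    <stem>_time_bin_means.xlsx
    <stem>_results.xlsx

Every output workbook carries a ``settings`` sheet; a sheet with that name
is accordingly ignored when reading, so outputs round-trip as inputs.
"""

from __future__ import annotations

import csv
import logging
import math
from pathlib import Path

import numpy as np
import openpyxl

from .model import (
    DesignError,
    GroupMatrix,
    PeriEventDataset,
    ResultsBundle,
    TimeBinSpec,
    ValidationError,
)

logger = logging.getLogger("periboot")

_EMPTY_OR_TEXT = "Non-numeric data found in Excel sheets or input file is empty"

__all__ = [
    "read_dataset",
    "validate_equal_columns",
    "write_dataset",
    "write_downsampled",
    "write_time_bin_means",
    "write_results",
]


def _is_number(cell: object) -> bool:
    return (
        isinstance(cell, (int, float))
        and not isinstance(cell, bool)
        and math.isfinite(cell)
    )


def _parse_sheet(rows: list[list[object]], sheet: str) -> tuple[tuple[str, ...], np.ndarray]:
    """Turn raw cell rows into (column labels, float matrix).

    Trailing all-empty rows/columns are trimmed (worksheets often carry
    stale dimensions); any empty cell inside the data rectangle is an
    error, as is any non-numeric cell.  The first row is treated as data
    when fully numeric, otherwise as column labels.
    """
    # trim trailing empty rows, then trailing empty columns
    while rows and all(c is None or c == "" for c in rows[-1]):
        rows.pop()
    width = 0
    for row in rows:
        cells = len(row)
        while cells and (row[cells - 1] is None or row[cells - 1] == ""):
            cells -= 1
        width = max(width, cells)
    if not rows or width == 0:
        raise ValidationError(f"sheet {sheet!r}: {_EMPTY_OR_TEXT}")

    grid = [list(r[:width]) + [None] * (width - len(r)) for r in rows]
    first = grid[0]
    if all(_is_number(c) for c in first):
        labels = tuple(str(i) for i in range(width))
        data_rows = grid
    else:
        labels = tuple("" if c is None else str(c) for c in first)
        data_rows = grid[1:]

    matrix = np.empty((len(data_rows), width), dtype=float)
    for i, row in enumerate(data_rows):
        for j, cell in enumerate(row):
            if _is_number(cell):
                matrix[i, j] = float(cell)
            elif isinstance(cell, str):
                try:
                    value = float(cell)
                except ValueError:
                    raise ValidationError(
                        f"sheet {sheet!r}, data row {i}, column {j}: "
                        f"{_EMPTY_OR_TEXT} (found {cell!r})"
                    ) from None
                if not math.isfinite(value):
                    raise ValidationError(
                        f"sheet {sheet!r}, data row {i}, column {j}: "
                        f"{_EMPTY_OR_TEXT} (found {cell!r})"
                    )
                matrix[i, j] = value
            else:
                raise ValidationError(
                    f"sheet {sheet!r}, data row {i}, column {j}: "
                    f"{_EMPTY_OR_TEXT} (found {cell!r})"
                )
    if matrix.shape[0] < 2:
        raise ValidationError(
            f"sheet {sheet!r}: at least 2 data rows (timepoints) are required"
        )
    return labels, matrix


def _read_xlsx(path: Path) -> list[GroupMatrix]:
    wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
    try:
        groups = []
        for ws in wb.worksheets:
            if ws.title.strip().lower() == "settings":
                continue
            rows = [list(r) for r in ws.iter_rows(values_only=True)]
            labels, matrix = _parse_sheet(rows, ws.title)
            groups.append(GroupMatrix(ws.title, matrix, labels))
    finally:
        wb.close()
    return groups


def _read_csv_dir(path: Path) -> list[GroupMatrix]:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".csv")
    if not files:
        raise ValidationError(f"{path}: no CSV files found. {_EMPTY_OR_TEXT}.")
    groups = []
    for f in files:
        with open(f, newline="") as fh:
            raw = [
                [None if cell.strip() == "" else cell.strip() for cell in row]
                for row in csv.reader(fh)
            ]
        # numeric-looking strings count as numbers for the header heuristic
        rows: list[list[object]] = []
        for row in raw:
            parsed: list[object] = []
            for cell in row:
                if cell is None:
                    parsed.append(None)
                else:
                    try:
                        parsed.append(float(cell))
                    except ValueError:
                        parsed.append(cell)
            rows.append(parsed)
        labels, matrix = _parse_sheet(rows, f.stem)
        groups.append(GroupMatrix(f.stem, matrix, labels))
    return groups


def read_dataset(path: str | Path) -> PeriEventDataset:
    """Read a group-per-sheet XLSX workbook (or CSV-per-group directory).

    Sheet order is preserved; CSV files are taken in sorted filename
    order.  The first row of each sheet is data when fully numeric and a
    header of column labels otherwise.  Raises :class:`ValidationError`
    for empty, non-numeric, blank-holed or ragged input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    groups = _read_csv_dir(path) if path.is_dir() else _read_xlsx(path)
    return PeriEventDataset(tuple(groups), source_path=str(path))


def validate_equal_columns(dataset: PeriEventDataset) -> None:
    """Require every group to carry the same number of animals/trials.

    Within-subjects analyses subtract groups column by column, so unequal
    counts are a design error; the between-groups analysis remains
    appropriate for such data.
    """
    counts = {g.name: g.n_subjects for g in dataset.groups}
    if len(set(counts.values())) > 1:
        raise DesignError(
            "within-groups analysis requires the same number of animals/trials "
            "in each Excel sheet; got "
            + ", ".join(f"{k}={v}" for k, v in counts.items())
            + ". With unequal counts it is appropriate to run the "
            "between-groups analysis."
        )


def _stem(dataset_path: str) -> str:
    return Path(dataset_path).stem if dataset_path else "dataset"


def _save(wb: openpyxl.Workbook, out: Path) -> Path:
    if out.exists():
        logger.warning("overwriting existing output file %s", out)
    try:
        wb.save(out)
    except OSError as exc:
        raise OSError(f"cannot write output workbook {out}: {exc}") from exc
    return out


def _settings_sheet(wb: openpyxl.Workbook, rows: list[tuple[str, str]]) -> None:
    ws = wb.create_sheet("settings")
    for key, value in rows:
        ws.append([key, value])


def write_dataset(dataset: PeriEventDataset, path: str | Path) -> Path:
    """Export a dataset as a group-per-sheet workbook (one header row of
    column labels, then one row per timepoint)."""
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for g in dataset.groups:
        ws = wb.create_sheet(g.name)
        ws.append(list(g.column_labels))
        for row in g.values:
            ws.append([float(v) for v in row])
    return _save(wb, Path(path))


def write_downsampled(
    dataset: PeriEventDataset, factor: int, out_dir: str | Path
) -> Path:
    """Downsample by ``factor`` and write ``<stem>_downsampled_<factor>.xlsx``."""
    from .preprocess import downsample  # local import: preprocess is pure

    reduced = downsample(dataset, factor)
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for g in reduced.groups:
        ws = wb.create_sheet(g.name)
        ws.append(list(g.column_labels))
        for row in g.values:
            ws.append([float(v) for v in row])
    _settings_sheet(
        wb,
        [
            ("downsample_factor", str(int(factor))),
            ("input_path", dataset.source_path),
        ],
    )
    out = Path(out_dir) / f"{_stem(dataset.source_path)}_downsampled_{int(factor)}.xlsx"
    return _save(wb, out)


def write_time_bin_means(table, bins: TimeBinSpec | None, out_dir: str | Path) -> Path:
    """Write a bin-means table as ``<stem>_time_bin_means.xlsx``.

    One sheet per group (rows = bins, columns = animals/trials) plus a
    settings sheet recording the bin count and each bin's inclusive
    (start, end) row indices.
    """
    bins = bins or table.bins
    wb = openpyxl.Workbook()
    wb.remove(wb.active)
    for name, frame in table.per_group.items():
        ws = wb.create_sheet(name)
        ws.append([str(c) for c in frame.columns])
        for row in frame.to_numpy():
            ws.append([float(v) for v in row])
    rows = [
        ("n_time_bins", str(len(bins.bins))),
        ("input_path", table.source_path),
    ]
    for i, (start, end) in enumerate(bins.bins):
        rows.append((f"bin {i} start row", str(start)))
        rows.append((f"bin {i} end row", str(end)))
    _settings_sheet(wb, rows)
    out = Path(out_dir) / f"{_stem(table.source_path)}_time_bin_means.xlsx"
    return _save(wb, out)


def render_p(p: float) -> str:
    """P values are reported to three decimals; '0.000' means p < 0.001."""
    return f"{p:.3f}"


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> Path:
    """Write the analysis results workbook ``<stem>_results.xlsx``.

    Four sheets: per-pair window statistics (mean differences, permutation
    p values to three decimals, and the list of significant timepoints),
    the per-timepoint binary maps for all group pairs, the per-group
    significance-from-baseline maps, and the run settings.  Full-precision
    p values live in the :class:`ResultsBundle`; only the rendering is
    rounded.
    """
    settings = bundle.settings
    wb = openpyxl.Workbook()
    wb.remove(wb.active)

    ws = wb.create_sheet("pairwise comparisons")
    ws.append(
        [
            "comparison",
            "baseline mean difference",
            "baseline p value",
            "comparison mean difference",
            "comparison p value",
            "significant time points",
        ]
    )
    for rec in bundle.pairwise:
        ws.append(
            [
                f"{rec.pair[0]} vs {rec.pair[1]}",
                float(rec.baseline.observed_mean_difference),
                render_p(rec.baseline.p_value),
                float(rec.comparison.observed_mean_difference),
                render_p(rec.comparison.p_value),
                ", ".join(str(i) for i in rec.significant_rows),
            ]
        )

    ws = wb.create_sheet("pairwise significance maps")
    ws.append([f"{a} vs {b}" for a, b in (rec.pair for rec in bundle.pairwise)])
    if bundle.pairwise:
        maps = np.column_stack([rec.map.flags for rec in bundle.pairwise])
        for row in maps:
            ws.append([int(v) for v in row])

    ws = wb.create_sheet("baseline significance maps")
    ws.append(list(bundle.baseline_maps))
    if bundle.baseline_maps:
        maps = np.column_stack([m.flags for m in bundle.baseline_maps.values()])
        for row in maps:
            ws.append([int(v) for v in row])

    _settings_sheet(wb, settings.to_rows() if settings else [])
    stem = _stem(settings.input_path if settings else "")
    return _save(wb, Path(out_dir) / f"{stem}_results.xlsx")
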