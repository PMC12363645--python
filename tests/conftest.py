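import numpy as np
import openpyxl
import pytest

from periboot import GroupMatrix, PeriEventDataset


@pytest.fixture
def make_workbook(tmp_path):
    """Write an XLSX workbook from {sheet: (header_or_None, rows)} specs."""

    def _make(sheets, name="mydata.xlsx"):
        wb = openpyxl.Workbook()
        wb.remove(wb.active)
        for sheet, (header, rows) in sheets.items():
            ws = wb.create_sheet(sheet)
            if header is not None:
                ws.append(list(header))
            for row in rows:
                ws.append(list(row))
        path = tmp_path / name
        wb.save(path)
        return path

    return _make


@pytest.fixture
def two_group_dataset():
    rng = np.random.default_rng(42)
    return PeriEventDataset(
        (
            GroupMatrix("A", rng.normal(size=(40, 5))),
            GroupMatrix("B", rng.normal(size=(40, 5))),
        ),
        source_path="mem",
    )


@pytest.fixture
def three_group_zero_dataset():
    zeros = np.zeros((30, 4))
    return PeriEventDataset(
        tuple(GroupMatrix(n, zeros) for n in ("A", "B", "C")),
        source_path="zeros",
    )
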