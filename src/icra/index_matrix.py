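"""Index-matrix data model and delimited-text I/O.

The input to InterCriteria analysis is a two-dimensional index matrix
[O, C, e]: a set of objects O (rows), a set of criteria C (columns) and a
real evaluation e_{O_i,C_k} of every object against every criterion.  For
docking data the objects are ligands and the criteria are scoring functions
(plus, optionally, an experimental affinity column); the evaluations are
unitless scores, RMSD values in angstroms, or -logK values depending on the
docking output considered.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["IndexMatrix", "read_matrix", "write_matrix", "transpose"]

_DELIMITERS = (",", ";", "\t")


class MatrixFormatError(ValueError):
    """Raised when a delimited file does not parse into a valid index matrix."""


@dataclass(frozen=True)
class IndexMatrix:
    """Objects x criteria evaluation table.

    Parameters
    ----------
    object_labels : sequence of str
        Row labels, unique, length m >= 2.
    criteria_labels : sequence of str
        Column labels, unique, length n >= 2.
    evaluations : (m, n) float array
        Finite evaluations e_{O_i,C_k}.
    """

    object_labels: tuple[str, ...]
    criteria_labels: tuple[str, ...]
    evaluations: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        obj = tuple(str(o) for o in self.object_labels)
        crit = tuple(str(c) for c in self.criteria_labels)
        ev = np.asarray(self.evaluations, dtype=float)
        if ev.ndim != 2:
            raise MatrixFormatError("evaluations must be a 2-D array")
        m, n = ev.shape
        if m < 2:
            raise MatrixFormatError(
                f"need at least 2 objects for pairwise comparison, got {m}"
            )
        if n < 2:
            raise MatrixFormatError(f"need at least 2 criteria, got {n}")
        if len(obj) != m or len(crit) != n:
            raise MatrixFormatError(
                f"label lengths ({len(obj)}, {len(crit)}) do not match "
                f"evaluations shape {ev.shape}"
            )
        if len(set(obj)) != m:
            raise MatrixFormatError("object labels are not unique")
        if len(set(crit)) != n:
            raise MatrixFormatError("criteria labels are not unique")
        if not np.isfinite(ev).all():
            i, k = np.argwhere(~np.isfinite(ev))[0]
            raise MatrixFormatError(
                f"non-finite evaluation at object {obj[i]!r}, criterion {crit[k]!r}"
            )
        object.__setattr__(self, "object_labels", obj)
        object.__setattr__(self, "criteria_labels", crit)
        ev.setflags(write=False)
        object.__setattr__(self, "evaluations", ev)

    @property
    def m(self) -> int:
        return self.evaluations.shape[0]

    @property
    def n(self) -> int:
        return self.evaluations.shape[1]

    def column(self, criterion: str) -> np.ndarray:
        """Evaluations of one criterion over all objects."""
        try:
            k = self.criteria_labels.index(criterion)
        except ValueError:
            raise KeyError(f"unknown criterion {criterion!r}") from None
        return self.evaluations[:, k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.array(self.evaluations),
            index=list(self.object_labels),
            columns=list(self.criteria_labels),
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IndexMatrix":
        return cls(
            object_labels=tuple(str(i) for i in df.index),
            criteria_labels=tuple(str(c) for c in df.columns),
            evaluations=df.to_numpy(dtype=float),
        )


def transpose(im: IndexMatrix) -> IndexMatrix:
    """Swap the object and criteria axes.  An involution."""
    return IndexMatrix(
        object_labels=im.criteria_labels,
        criteria_labels=im.object_labels,
        evaluations=im.evaluations.T.copy(),
    )


def _detect_delimiter(header: str) -> str:
    counts = {d: header.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[best] == 0:
        raise MatrixFormatError(
            "could not detect a delimiter (expected comma, semicolon or tab)"
        )
    return best


def _parse_cell(raw: str, row_label: str, col_label: str) -> float:
    text = raw.strip()
    try:
        return float(text)
    except ValueError:
        pass
    # 1,23-style decimals come from locale-formatted spreadsheets; refuse
    # rather than guess, so 1,234 is never silently read as 1234 or 1.234.
    if text and text.replace(",", ".", 1).replace(".", "", 1).lstrip("+-").isdigit():
        raise MatrixFormatError(
            f"cell at object {row_label!r}, criterion {col_label!r} uses a comma "
            f"decimal separator ({text!r}); use '.' as the decimal separator"
        )
    raise MatrixFormatError(
        f"non-numeric cell {text!r} at object {row_label!r}, criterion {col_label!r}"
    )


def read_matrix(
    source: str | Path | io.TextIOBase,
    orientation: str = "objects_as_rows",
    delimiter: str | None = None,
) -> IndexMatrix:
    """Read a delimited evaluation table into an :class:`IndexMatrix`.

    The file must have one header row of labels and one leading label column.
    With ``orientation="criteria_as_rows"`` the parsed table is transposed so
    that the returned matrix always has objects as rows.  The delimiter is
    auto-detected among comma/semicolon/tab unless given.
    """
    if orientation not in ("objects_as_rows", "criteria_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, (str, Path)):
        text = str(source)
    else:
        text = source.read()

    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 3:
        raise MatrixFormatError(
            f"need a header row and at least 2 data rows, got {len(lines)} line(s)"
        )
    delim = delimiter or _detect_delimiter(lines[0])

    header = [c.strip() for c in lines[0].split(delim)]
    col_labels = header[1:]  # first header cell is the axis corner, ignored
    width = len(header)
    row_labels: list[str] = []
    rows: list[list[float]] = []
    for ln in lines[1:]:
        cells = [c.strip() for c in ln.split(delim)]
        if len(cells) != width:
            raise MatrixFormatError(
                f"ragged row {cells[0]!r}: expected {width} cells, got {len(cells)}"
            )
        row_labels.append(cells[0])
        rows.append(
            [
                _parse_cell(raw, cells[0], col)
                for raw, col in zip(cells[1:], col_labels)
            ]
        )

    im = IndexMatrix(
        object_labels=tuple(row_labels),
        criteria_labels=tuple(col_labels),
        evaluations=np.array(rows, dtype=float),
    )
    if orientation == "criteria_as_rows":
        im = transpose(im)
    return im


def write_matrix(im: IndexMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write the matrix in the same header-row/label-column layout read_matrix expects."""
    with open(path, "w") as fh:
        fh.write(delimiter.join(["object", *im.criteria_labels]) + "\n")
        for label, row in zip(im.object_labels, np.asarray(im.evaluations)):
            fh.write(delimiter.join([label, *(repr(float(v)) for v in row)]) + "\n")
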