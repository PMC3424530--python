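"""Shared container and text format for expected-weight-change surfaces.

Orientation convention: rows are indexed by the first axis (synchronization
window T, ascending) and columns by the second axis (effective delay d,
ascending).  The file format is tab-delimited text: ``#``-prefixed header
lines carry metadata; the first data row holds the column axis, the first
column of each following row holds the row-axis value.  Masked (invalid)
cells serialize as the token ``NA``.  An optional standard-error matrix
follows after a ``# stderr`` marker line with the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["WeightChangeSurface", "save_surface", "load_surface"]

_MASK_TOKEN = "NA"


@dataclass
class WeightChangeSurface:
    """Grid of expected weight change (or equilibrium weight) over two parameters."""

    axis1_name: str
    axis1: np.ndarray
    axis2_name: str
    axis2: np.ndarray
    values: np.ndarray
    stderr: np.ndarray | None = None
    mask: np.ndarray | None = None  # True where the cell is invalid/masked
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis1 = np.asarray(self.axis1, dtype=float)
        self.axis2 = np.asarray(self.axis2, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.axis1.size, self.axis2.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match axes "
                f"({self.axis1.size}, {self.axis2.size})"
            )
        for name, arr in (("stderr", self.stderr), ("mask", self.mask)):
            if arr is not None and np.asarray(arr).shape != self.values.shape:
                raise ValueError(f"{name} shape does not match values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)

    def value_at(self, a1: float, a2: float) -> float:
        """Value at the cell whose axis coordinates are closest to (a1, a2)."""
        i = int(np.argmin(np.abs(self.axis1 - a1)))
        j = int(np.argmin(np.abs(self.axis2 - a2)))
        return float(self.values[i, j])


def _format_cell(x: float, masked: bool) -> str:
    return _MASK_TOKEN if masked or not np.isfinite(x) else repr(float(x))


def _matrix_lines(surface: WeightChangeSurface, matrix: np.ndarray) -> list[str]:
    mask = surface.mask if surface.mask is not None else np.zeros_like(matrix, dtype=bool)
    corner = f"{surface.axis1_name}\\{surface.axis2_name}"
    lines = ["\t".join([corner] + [repr(float(v)) for v in surface.axis2])]
    for i, a1 in enumerate(surface.axis1):
        cells = [_format_cell(matrix[i, j], mask[i, j]) for j in range(surface.axis2.size)]
        lines.append("\t".join([repr(float(a1))] + cells))
    return lines


def save_surface(surface: WeightChangeSurface, path) -> None:
    lines = [
        "# stdpsync weight-change surface",
        f"# orientation: rows={surface.axis1_name} ascending, "
        f"columns={surface.axis2_name} ascending",
    ]
    for key in sorted(surface.meta):
        lines.append(f"# {key}: {surface.meta[key]}")
    lines.extend(_matrix_lines(surface, surface.values))
    if surface.stderr is not None:
        lines.append("# stderr")
        lines.extend(_matrix_lines(surface, surface.stderr))
    Path(path).write_text("\n".join(lines) + "\n")


def _parse_matrix(lines: list[str]) -> tuple[str, str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    header = lines[0].split("\t")
    axis1_name, axis2_name = header[0].split("\\", 1)
    axis2 = np.array([float(v) for v in header[1:]])
    axis1, rows, mask_rows = [], [], []
    for line in lines[1:]:
        cells = line.split("\t")
        axis1.append(float(cells[0]))
        rows.append([np.nan if c == _MASK_TOKEN else float(c) for c in cells[1:]])
        mask_rows.append([c == _MASK_TOKEN for c in cells[1:]])
    return (axis1_name, axis2_name, np.array(axis1), axis2,
            np.array(rows), np.array(mask_rows, dtype=bool))


def load_surface(path) -> WeightChangeSurface:
    meta: dict = {}
    data_lines: list[str] = []
    stderr_lines: list[str] = []
    target = data_lines
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            body = raw[1:].strip()
            if body == "stderr":
                target = stderr_lines
            elif ":" in body and not body.startswith("stdpsync"):
                key, value = (p.strip() for p in body.split(":", 1))
                if key != "orientation":
                    meta[key] = value
        elif raw.strip():
            target.append(raw)
    axis1_name, axis2_name, axis1, axis2, values, mask = _parse_matrix(data_lines)
    stderr = None
    if stderr_lines:
        stderr = _parse_matrix(stderr_lines)[4]
    return WeightChangeSurface(
        axis1_name=axis1_name, axis1=axis1, axis2_name=axis2_name, axis2=axis2,
        values=values, stderr=stderr,
        mask=mask if mask.any() else None, meta=meta,
    )
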