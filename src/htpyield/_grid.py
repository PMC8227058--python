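"""Plot-index <-> grid-coordinate mapping shared by layout, rendering and extraction."""

from __future__ import annotations

NUMBERINGS = ("row_major", "serpentine")


def index_to_rowcol(k: int, n_cols: int, numbering: str = "row_major") -> tuple[int, int]:
    """Map a 0-based plot index to a 0-based (row, col) grid position.

    ``serpentine`` reverses the column direction on odd rows, the common
    field-book ordering where the planter turns at the end of each pass.
    """
    if numbering not in NUMBERINGS:
        raise ValueError(f"numbering must be one of {NUMBERINGS}, got {numbering!r}")
    row, col = divmod(k, n_cols)
    if numbering == "serpentine" and row % 2 == 1:
        col = n_cols - 1 - col
    return row, col


def rowcol_to_index(row: int, col: int, n_cols: int, numbering: str = "row_major") -> int:
    """Inverse of :func:`index_to_rowcol` (0-based everywhere)."""
    if numbering not in NUMBERINGS:
        raise ValueError(f"numbering must be one of {NUMBERINGS}, got {numbering!r}")
    if numbering == "serpentine" and row % 2 == 1:
        col = n_cols - 1 - col
    return row * n_cols + col
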