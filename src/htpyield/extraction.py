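"""Slice an orthomosaic raster into per-plot patches on a regular grid.

Pixel coordinates are 0-based with half-open windows [x0, x1) x [y0, y1);
patches are pixel copies (no resampling). Plot numbering follows the trial's
row-major or serpentine convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._grid import NUMBERINGS, index_to_rowcol


@dataclass(frozen=True)
class GridConfig:
    origin_px: tuple[int, int]  # (x, y) of plot 1's top-left corner
    patch_w_px: int
    patch_h_px: int
    gap_x_px: int
    gap_y_px: int
    n_rows: int
    n_cols: int
    numbering: str = "row_major"
    expected_plots: int | None = None

    def validate(self) -> None:
        for name in ("patch_w_px", "patch_h_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("gap_x_px", "gap_y_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.numbering not in NUMBERINGS:
            raise ValueError(f"unknown numbering {self.numbering!r}")
        n = self.expected_plots if self.expected_plots is not None else self.n_rows * self.n_cols
        if self.n_rows * self.n_cols < n:
            raise ValueError("grid smaller than expected_plots")

    @property
    def n_plots(self) -> int:
        return self.expected_plots if self.expected_plots is not None else self.n_rows * self.n_cols

    def window(self, plot_id: int) -> tuple[int, int, int, int]:
        """Half-open pixel window (x0, y0, x1, y1) of a 1-based plot id."""
        row, col = index_to_rowcol(plot_id - 1, self.n_cols, self.numbering)
        x0 = self.origin_px[0] + col * (self.patch_w_px + self.gap_x_px)
        y0 = self.origin_px[1] + row * (self.patch_h_px + self.gap_y_px)
        return x0, y0, x0 + self.patch_w_px, y0 + self.patch_h_px

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, default=list, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "GridConfig":
        d = json.loads(Path(path).read_text())
        d["origin_px"] = tuple(d["origin_px"])
        return cls(**d)


@dataclass
class PlotImage:
    """An RGB patch for one plot; window is its source rectangle in the mosaic."""

    plot_id: int
    pixels: np.ndarray  # (H, W, 3) uint8
    window: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be uint8")

    def save_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.pixels).save(path)

    @classmethod
    def load_png(cls, path: str | Path, plot_id: int) -> "PlotImage":
        from PIL import Image

        return cls(plot_id, np.asarray(Image.open(path).convert("RGB")))


def extract_plots(mosaic: np.ndarray, grid: GridConfig) -> list[PlotImage]:
    """Cut the mosaic into plot patches numbered per the grid's convention.

    Raises a geometry error naming the first plot whose window leaves the
    raster, and a format error for non 3-band rasters.
    """
    grid.validate()
    if mosaic.ndim != 3 or mosaic.shape[2] != 3:
        raise ValueError(f"mosaic must be a 3-band (H, W, 3) raster, got shape {mosaic.shape}")
    H, W = mosaic.shape[:2]
    patches: list[PlotImage] = []
    for pid in range(1, grid.n_plots + 1):
        x0, y0, x1, y1 = grid.window(pid)
        if x0 < 0 or y0 < 0 or x1 > W or y1 > H:
            raise ValueError(
                f"plot {pid}: window ({x0},{y0})-({x1},{y1}) outside raster {W}x{H}"
            )
        patches.append(PlotImage(pid, np.ascontiguousarray(mosaic[y0:y1, x0:x1]),
                                 window=(x0, y0, x1, y1)))
    return patches


def write_patches(patches: list[PlotImage], outdir: str | Path) -> pd.DataFrame:
    """Write plot_{id:04d}.png files plus a window manifest; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        name = f"plot_{p.plot_id:04d}.png"
        p.save_png(outdir / name)
        x0, y0, x1, y1 = p.window if p.window else (0, 0, p.pixels.shape[1], p.pixels.shape[0])
        rows.append({"plot_id": p.plot_id, "file": name, "x0": x0, "y0": y0, "x1": x1, "y1": y1})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
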