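"""Synthetic plot-image and orthomosaic rendering.

Each plot is drawn as ten plant canopies (two rows of five, matching the field
planting) on a soil background. The expected green-canopy cover is a
saturating, strictly increasing function of the plot's green (fresh) matter:

    cover(g) = cover_max * (1 - exp(-canopy_gain * g))

so images carry a learnable but bounded signal about yield — canopy cover
saturates as plants close over the inter-row, exactly the regime where
image-based biomass estimation degrades. Hue noise perturbs pixel colors and
texture noise perturbs per-plant canopy size.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .extraction import GridConfig, PlotImage
from .layout import TrialLayout
from .simulate import PlotTruth


@dataclass(frozen=True)
class RenderParams:
    patch_px: int = 64
    plants_per_plot: int = 10  # 2 rows of 5
    canopy_gain: float = 0.25  # per kg green matter
    cover_max: float = 0.85
    hue_noise_sd: float = 10.0  # 8-bit counts
    texture_noise_sd: float = 0.05  # relative canopy-radius jitter
    soil_color: tuple[int, int, int] = (115, 92, 66)
    plant_color: tuple[int, int, int] = (62, 138, 70)
    mosaic_gap_px: int = 8

    def validate(self) -> None:
        if self.patch_px < 32:
            raise ValueError("patch_px must be >= 32")
        if self.hue_noise_sd < 0 or self.texture_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not 0 < self.cover_max <= 1:
            raise ValueError("cover_max must be in (0, 1]")
        if self.canopy_gain <= 0:
            raise ValueError("canopy_gain must be positive")


@dataclass
class MosaicRaster:
    pixels: np.ndarray  # (H, W, 3) uint8
    grid: GridConfig

    def save(self, path: str | Path) -> None:
        """TIFF via tifffile for .tif/.tiff, else PNG; grid metadata as JSON sidecar."""
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            tifffile.imwrite(path, self.pixels)
        else:
            from PIL import Image

            Image.fromarray(self.pixels).save(path)
        self.grid.to_json(path.with_suffix(".grid.json"))

    @classmethod
    def load(cls, path: str | Path) -> "MosaicRaster":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            px = tifffile.imread(path)
        else:
            from PIL import Image

            px = np.asarray(Image.open(path).convert("RGB"))
        return cls(np.asarray(px, dtype=np.uint8), GridConfig.from_json(path.with_suffix(".grid.json")))


def expected_cover(green_matter_kg: float, rp: RenderParams) -> float:
    """Target green-canopy cover fraction for a given plot green matter."""
    return rp.cover_max * (1.0 - np.exp(-rp.canopy_gain * max(green_matter_kg, 0.0)))


def render_plot_image(truth: PlotTruth, rp: RenderParams = RenderParams(), seed: int = 0) -> PlotImage:
    """Render one plot patch; deterministic per seed.

    With both noise sds at zero, the realized canopy area is a monotone
    function of green matter for a fixed seed (plant centers fixed, radii
    strictly increasing in cover).
    """
    rp.validate()
    rng = np.random.default_rng(seed)
    n = rp.patch_px
    img = np.empty((n, n, 3), dtype=np.float64)
    img[:] = rp.soil_color
    # soil texture speckle
    img += rng.normal(0.0, rp.hue_noise_sd / 2.0, size=img.shape)

    cover = expected_cover(truth.true_green_matter, rp)
    if cover > 0.0:
        n_rows_plants, n_per_row = 2, rp.plants_per_plot // 2
        target_area = cover * n * n
        base_r = np.sqrt(target_area / (np.pi * rp.plants_per_plot))
        yy, xx = np.mgrid[0:n, 0:n]
        canopy = np.zeros((n, n), dtype=bool)
        for i in range(n_rows_plants):
            cy = (i + 0.5) / n_rows_plants * n + rng.normal(0, 0.02 * n)
            for j in range(n_per_row):
                cx = (j + 0.5) / n_per_row * n + rng.normal(0, 0.02 * n)
                r = base_r * max(1.0 + rng.normal(0.0, rp.texture_noise_sd), 0.0)
                canopy |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
        plant = np.array(rp.plant_color, dtype=np.float64)
        img[canopy] = plant + rng.normal(0.0, rp.hue_noise_sd, size=(int(canopy.sum()), 3))

    return PlotImage(truth.plot_id, np.clip(img, 0, 255).astype(np.uint8))


def render_trial_images(truths: list[PlotTruth], rp: RenderParams = RenderParams(),
                        seed: int = 0) -> list[PlotImage]:
    """One patch per plot, each with an independent per-plot substream."""
    ss = np.random.SeedSequence(seed).spawn(len(truths))
    return [
        render_plot_image(t, rp, seed=int(s.generate_state(1)[0] % (2**31)))
        for t, s in zip(truths, ss)
    ]


def green_canopy_fraction(img: PlotImage | np.ndarray, margin: int = 10) -> float:
    """Fraction of pixels whose green channel dominates red and blue by `margin`."""
    px = img.pixels if isinstance(img, PlotImage) else img
    px = px.astype(np.int16)
    green = (px[..., 1] > px[..., 0] + margin) & (px[..., 1] > px[..., 2] + margin)
    return float(green.mean())


def render_orthomosaic(layout: TrialLayout, images: list[PlotImage],
                       rp: RenderParams = RenderParams()) -> MosaicRaster:
    """Assemble plot patches into one raster on the layout grid.

    Patches are separated by ``mosaic_gap_px`` of soil background; raster size
    is n_rows*patch + (n_rows+1)*gap by n_cols*patch + (n_cols+1)*gap.
    """
    rp.validate()
    if not layout.plots:
        raise ValueError("layout has no plots")
    by_id = {im.plot_id: im for im in images}
    missing = [p.plot_id for p in layout.plots if p.plot_id not in by_id]
    if missing:
        raise ValueError(f"missing images for plots {missing[:5]}")
    sizes = {im.pixels.shape for im in images}
    if len(sizes) != 1:
        raise ValueError(f"non-uniform patch sizes: {sizes}")
    ph, pw = images[0].pixels.shape[:2]

    gap = rp.mosaic_gap_px
    H = layout.n_rows * ph + (layout.n_rows + 1) * gap
    W = layout.n_cols * pw + (layout.n_cols + 1) * gap
    raster = np.empty((H, W, 3), dtype=np.uint8)
    raster[:] = rp.soil_color

    grid = GridConfig(
        origin_px=(gap, gap),
        patch_w_px=pw,
        patch_h_px=ph,
        gap_x_px=gap,
        gap_y_px=gap,
        n_rows=layout.n_rows,
        n_cols=layout.n_cols,
        numbering=layout.numbering,
        expected_plots=layout.n_plots,
    )
    for p in layout.plots:
        x0, y0, x1, y1 = grid.window(p.plot_id)
        raster[y0:y1, x0:x1] = by_id[p.plot_id].pixels
    return MosaicRaster(raster, grid)
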