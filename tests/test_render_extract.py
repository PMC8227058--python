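"""Rendering signal and orthomosaic round-trip checks."""

import numpy as np
import pytest
from scipy.stats import spearmanr

import htpyield as h
from htpyield.render import RenderParams, green_canopy_fraction, render_plot_image
from htpyield.simulate import PlotTruth


def _truth(plot_id=1, green=3.0):
    return PlotTruth(plot_id, 2000.0, 1100.0, 800.0, 100.0, green, 0.0, 0.0, 0.0)


def test_empty_plot_is_soil_only():
    img = render_plot_image(_truth(green=0.0), seed=0)
    assert green_canopy_fraction(img) < 0.05


def test_canopy_monotone_in_green_matter_without_noise():
    rp = RenderParams(hue_noise_sd=0.0, texture_noise_sd=0.0)
    f1 = green_canopy_fraction(render_plot_image(_truth(green=1.0), rp, seed=7))
    f2 = green_canopy_fraction(render_plot_image(_truth(green=3.0), rp, seed=7))
    f3 = green_canopy_fraction(render_plot_image(_truth(green=6.0), rp, seed=7))
    assert f1 < f2 < f3


def test_render_deterministic_per_seed():
    a = render_plot_image(_truth(), seed=5)
    b = render_plot_image(_truth(), seed=5)
    c = render_plot_image(_truth(), seed=6)
    assert (a.pixels == b.pixels).all()
    assert (a.pixels != c.pixels).any()


def test_canopy_signal_over_simulated_trial(default_truths, default_images):
    """At default noise the measured canopy cover tracks green matter (Spearman > 0.95)."""
    g = np.array([t.true_green_matter for t in default_truths])
    frac = np.array([green_canopy_fraction(im) for im in default_images])
    assert spearmanr(frac, g).statistic > 0.95


def test_mosaic_dimensions(default_layout, default_images):
    rp = RenderParams(mosaic_gap_px=8)
    mosaic = h.render_orthomosaic(default_layout, default_images, rp)
    ph = default_images[0].pixels.shape[0]
    H = default_layout.n_rows * ph + (default_layout.n_rows + 1) * 8
    W = default_layout.n_cols * ph + (default_layout.n_cols + 1) * 8
    assert mosaic.pixels.shape == (H, W, 3)


def test_mosaic_extract_roundtrip_pixel_identical(default_layout, default_images):
    mosaic = h.render_orthomosaic(default_layout, default_images)
    patches = h.extract_plots(mosaic.pixels, mosaic.grid)
    assert len(patches) == 330
    by_id = {im.plot_id: im for im in default_images}
    for p in patches:
        assert (p.pixels == by_id[p.plot_id].pixels).all()


def test_mosaic_file_roundtrip(tmp_path, default_layout, default_images):
    mosaic = h.render_orthomosaic(default_layout, default_images)
    mosaic.save(tmp_path / "m.tif")
    back = h.MosaicRaster.load(tmp_path / "m.tif")
    assert (back.pixels == mosaic.pixels).all()
    assert back.grid == mosaic.grid


def test_missing_image_rejected(default_layout, default_images):
    with pytest.raises(ValueError):
        h.render_orthomosaic(default_layout, default_images[:-1])


def test_empty_layout_rejected(default_images):
    empty = h.TrialLayout(plots=[], n_rows=0, n_cols=0, n_reps=0,
                          blocks_per_rep=0, plot_area_m2=4.5)
    with pytest.raises(ValueError):
        h.render_orthomosaic(empty, default_images)


def test_extraction_window_disjointness():
    grid = h.GridConfig(origin_px=(4, 4), patch_w_px=10, patch_h_px=10,
                        gap_x_px=2, gap_y_px=2, n_rows=3, n_cols=4)
    windows = [grid.window(pid) for pid in range(1, 13)]
    for i, a in enumerate(windows):
        for b in windows[i + 1:]:
            no_overlap = a[2] <= b[0] or b[2] <= a[0] or a[3] <= b[1] or b[3] <= a[1]
            assert no_overlap


def test_out_of_bounds_window_error():
    mosaic = np.zeros((20, 20, 3), dtype=np.uint8)
    grid = h.GridConfig(origin_px=(15, 15), patch_w_px=10, patch_h_px=10,
                        gap_x_px=0, gap_y_px=0, n_rows=1, n_cols=1)
    with pytest.raises(ValueError, match="plot 1"):
        h.extract_plots(mosaic, grid)


def test_non_rgb_raster_rejected():
    grid = h.GridConfig(origin_px=(0, 0), patch_w_px=4, patch_h_px=4,
                        gap_x_px=0, gap_y_px=0, n_rows=1, n_cols=1)
    with pytest.raises(ValueError, match="3-band"):
        h.extract_plots(np.zeros((10, 10), dtype=np.uint8), grid)


def test_serpentine_numbering_matches_layout():
    cfg = h.DesignConfig(n_families=4, n_genitors_sexual=0, n_genitors_apomictic=0,
                         n_cultivar_checks=2, n_reps=2, blocks_per_rep=2,
                         n_field_rows=4, n_field_cols=3, numbering="serpentine")
    layout = h.make_layout(cfg, seed=0)
    truths = h.simulate_trial(layout, seed=0)
    from htpyield.render import render_trial_images

    imgs = render_trial_images(truths, seed=0)
    mosaic = h.render_orthomosaic(layout, imgs)
    patches = h.extract_plots(mosaic.pixels, mosaic.grid)
    by_id = {im.plot_id: im for im in imgs}
    for p in patches:
        assert (p.pixels == by_id[p.plot_id].pixels).all()
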