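"""Staged orchestration: simulate -> render -> extract -> train -> metrics -> genetics -> selection.

Each stage writes plain-text artifacts (CSV/JSON) into the run directory and
later stages reload them from disk when not already in memory, so stages can
be run in one shot or one at a time. The resolved configuration and the seed
are serialized alongside the artifacts for provenance.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cnn import crossval_predict
from .config import RunConfig
from .extraction import PlotImage, extract_plots, write_patches
from .layout import TrialLayout, make_layout
from .metrics import MetricSet, aggregate_folds, elbow_bins, histogram_intersection
from .mixed_model import SpatialMixedModel, genetic_correlation
from .render import MosaicRaster, render_orthomosaic, render_trial_images
from .selection import scenario_table
from .simulate import derive_field_samples, simulate_trial, truths_to_dataframe
from .traits import plot_yields, samples_from_dataframe, samples_to_dataframe

logger = logging.getLogger(__name__)

TRAIT_COLUMN = {"TDMY": "tdmy_kg_ha", "LDMY": "ldmy_kg_ha"}


class PipelineState:
    """Lazy artifact store for one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.layout: TrialLayout | None = None
        self.truths = None
        self.samples = None
        self.traits_df: pd.DataFrame | None = None
        self.images: list[PlotImage] | None = None
        self.mosaic: MosaicRaster | None = None
        self.patches: list[PlotImage] | None = None
        self.htp_df: pd.DataFrame | None = None
        self.genetics: dict | None = None

    # -- loaders -----------------------------------------------------------
    def need_layout(self) -> TrialLayout:
        if self.layout is None:
            path = self.outdir / "layout.csv"
            if not path.exists():
                raise FileNotFoundError(f"{path} missing; run the simulate stage first")
            self.layout = TrialLayout.from_dataframe(
                pd.read_csv(path),
                plot_area_m2=self.config.design.plot_area_m2,
                numbering=self.config.design.numbering,
            )
        return self.layout

    def need_traits(self) -> pd.DataFrame:
        if self.traits_df is None:
            path = self.outdir / "traits.csv"
            if not path.exists():
                raise FileNotFoundError(f"{path} missing; run the simulate stage first")
            self.traits_df = pd.read_csv(path)
        return self.traits_df

    def need_patches(self) -> list[PlotImage]:
        if self.patches is None:
            mosaic_path = self.outdir / "mosaic.tif"
            if not mosaic_path.exists():
                raise FileNotFoundError(f"{mosaic_path} missing; run the render stage first")
            mosaic = MosaicRaster.load(mosaic_path)
            self.patches = extract_plots(mosaic.pixels, mosaic.grid)
        return self.patches

    def need_htp(self) -> pd.DataFrame:
        if self.htp_df is None:
            path = self.outdir / "htp_trait.csv"
            if not path.exists():
                raise FileNotFoundError(f"{path} missing; run the train stage first")
            self.htp_df = pd.read_csv(path)
        return self.htp_df


def stage_simulate(state: PipelineState) -> None:
    cfg = state.config
    layout = make_layout(cfg.design.to_dataclass(), seed=cfg.seed)
    params = cfg.genetic.to_dataclass()
    truths = simulate_trial(layout, params, seed=cfg.seed + 1)
    samples = derive_field_samples(truths, layout, params, seed=cfg.seed + 2)
    traits = plot_yields(samples, layout.plot_area_m2)

    layout.to_dataframe().to_csv(state.outdir / "layout.csv", index=False)
    truths_to_dataframe(truths).to_csv(state.outdir / "truth.csv", index=False)
    samples_to_dataframe(samples).to_csv(state.outdir / "samples.csv", index=False)
    traits.to_csv(state.outdir / "traits.csv", index=False)
    state.layout, state.truths, state.samples, state.traits_df = layout, truths, samples, traits


def stage_render(state: PipelineState) -> None:
    cfg = state.config
    layout = state.need_layout()
    if state.truths is None:
        truth_df = pd.read_csv(state.outdir / "truth.csv")
        from .simulate import PlotTruth

        state.truths = [
            PlotTruth(plot_id=int(row["plot_id"]),
                      **{k: float(row[k]) for k in PlotTruth.__dataclass_fields__
                         if k != "plot_id"})
            for _, row in truth_df.iterrows()
        ]
    rp = cfg.render.to_dataclass()
    images = render_trial_images(state.truths, rp, seed=cfg.seed + 3)
    mosaic = render_orthomosaic(layout, images, rp)
    mosaic.save(state.outdir / "mosaic.tif")
    state.images, state.mosaic = images, mosaic


def stage_extract(state: PipelineState) -> None:
    if state.mosaic is None:
        state.mosaic = MosaicRaster.load(state.outdir / "mosaic.tif")
    patches = extract_plots(state.mosaic.pixels, state.mosaic.grid)
    write_patches(patches, state.outdir / "patches")
    state.patches = patches


def stage_train(state: PipelineState) -> None:
    cfg = state.config
    patches = state.need_patches()
    traits = state.need_traits()
    col = TRAIT_COLUMN[cfg.trait]
    y = traits.set_index("plot_id").loc[[p.plot_id for p in patches], col].to_numpy()
    t = cfg.train
    htp = crossval_predict(
        patches, y, arch=t.arch, k=t.k_folds, seed=cfg.seed + 4, trait_name=cfg.trait,
        input_px=t.input_px, learning_rate=t.learning_rate, beta1=t.beta1, beta2=t.beta2,
        adam_eps=t.adam_eps, epochs=t.epochs, batch_size=t.batch_size,
        early_stop_interval=t.early_stop_interval, val_fraction=t.val_fraction,
        augment=t.augment,
    )
    df = pd.DataFrame({"plot_id": htp.plot_ids, "fold": htp.folds, "y": y, "yhat": htp.values})
    df.to_csv(state.outdir / "htp_trait.csv", index=False)
    pd.DataFrame([m.__dict__ for m in htp.fold_metrics]).to_csv(
        state.outdir / "fold_metrics.csv", index=False
    )
    state.htp_df = df


def stage_metrics(state: PipelineState) -> None:
    cfg = state.config
    df = state.need_htp()
    folds_path = state.outdir / "fold_metrics.csv"
    fold_sets = [
        MetricSet(int(r.n), r.mae, r.rmse, r.r, bool(r.r_defined))
        for r in pd.read_csv(folds_path).itertuples()
    ]
    summary = aggregate_folds(fold_sets)
    n_bins = cfg.n_bins if cfg.n_bins is not None else elbow_bins(df.y.to_numpy())
    inter = histogram_intersection(df.y.to_numpy(), df.yhat.to_numpy(), n_bins=n_bins)
    from .metrics import regression_metrics

    overall = regression_metrics(df.y.to_numpy(), df.yhat.to_numpy())
    out = {
        "overall": {"n": overall.n, "mae": overall.mae, "rmse": overall.rmse, "r": overall.r},
        "fold_mean": summary.mean,
        "fold_sd": summary.sd,
        "histogram_intersection": inter,
        "n_bins": int(n_bins),
    }
    (state.outdir / "metrics.json").write_text(json.dumps(out, indent=2))


def stage_genetics(state: PipelineState) -> None:
    cfg = state.config
    layout_df = state.need_layout().to_dataframe()
    traits = state.need_traits()
    col = TRAIT_COLUMN[cfg.trait]
    merged = layout_df.merge(traits[["plot_id", col]], on="plot_id")
    htp = state.need_htp().rename(columns={"yhat": "htp"})
    merged = merged.merge(htp[["plot_id", "htp"]], on="plot_id")

    g = cfg.genetics
    m_real = SpatialMixedModel(fit_rho=g.fit_rho, max_iter=g.max_iter).fit(merged, merged[col])
    m_htp = SpatialMixedModel(fit_rho=g.fit_rho, max_iter=g.max_iter).fit(merged, merged["htp"])
    r = genetic_correlation(m_real.fit_, m_htp.fit_)
    out = {
        "trait": cfg.trait,
        "real": {"Vg": m_real.Vg_, "Vb": m_real.Vb_, "Ve": m_real.Ve_,
                 "rho_row": m_real.rho_row_, "rho_col": m_real.rho_col_,
                 "H": m_real.H_, "converged": m_real.converged_},
        "htp": {"Vg": m_htp.Vg_, "Vb": m_htp.Vb_, "Ve": m_htp.Ve_,
                "rho_row": m_htp.rho_row_, "rho_col": m_htp.rho_col_,
                "H": m_htp.H_, "converged": m_htp.converged_},
        "genetic_correlation": r,
    }
    (state.outdir / "genetics.json").write_text(json.dumps(out, indent=2))
    pd.DataFrame({
        "family": m_real.family_labels_,
        "blup_real": m_real.blup_family_,
        "blup_htp": m_htp.blup_family_,
    }).to_csv(state.outdir / "blups.csv", index=False)
    state.genetics = out


def stage_selection(state: PipelineState) -> None:
    from .mixed_model import GeneticSummary

    cfg = state.config
    if cfg.selection_input is not None:
        si = cfg.selection_input
        real = GeneticSummary(cfg.trait, si.real_Vg, si.real_H, 1.0)
        htp = GeneticSummary(cfg.trait, float("nan"), si.htp_H, si.htp_r)
    else:
        if state.genetics is None:
            path = state.outdir / "genetics.json"
            if not path.exists():
                raise FileNotFoundError(f"{path} missing; run the genetics stage first")
            state.genetics = json.loads(path.read_text())
        gen = state.genetics
        real = GeneticSummary(cfg.trait, gen["real"]["Vg"], gen["real"]["H"], 1.0)
        htp = GeneticSummary(cfg.trait, gen["htp"]["Vg"], gen["htp"]["H"],
                             gen["genetic_correlation"])
    scenarios = [s.to_dataclass() for s in cfg.scenarios]
    table = scenario_table(real, htp, scenarios, trait=cfg.trait)
    table.to_dataframe().to_csv(state.outdir / "selection.csv", index=False)
    table.printed().to_csv(state.outdir / "selection_printed.csv", index=False)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "render": stage_render,
    "extract": stage_extract,
    "train": stage_train,
    "metrics": stage_metrics,
    "genetics": stage_genetics,
    "selection": stage_selection,
}


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    A stage failure halts the run with the stage named; artifacts written by
    completed stages are preserved.
    """
    state = PipelineState(config)
    config.to_yaml(state.outdir / "config.resolved.yaml")
    (state.outdir / "run.json").write_text(json.dumps(
        {"seed": config.seed, "version": __version__, "stages": config.stages}, indent=2
    ))
    for name in [s for s in _STAGE_FUNCS if s in config.stages]:
        logger.info("stage %s", name)
        try:
            _STAGE_FUNCS[name](state)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
    return state.outdir
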