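"""Generative model of the trial: genetic, block and spatially correlated residual effects.

Per-plot total dry matter yield (TDMY, kg/ha) is assembled additively,

    y = mu + rep + (family | check) + block + e,

with family effects ~ N(0, Vg) drawn once per family and shared across its
replicated plots, block-within-rep effects ~ N(0, Vb), and the residual field
e ~ N(0, Ve * R) where R = AR1(rho_row) (x) AR1(rho_col) over the field grid —
the separable first-order autoregressive structure commonly fitted to row/column
trends in field trials. Yields are truncated at zero (biological floor).

Each plot's TDMY is then decomposed into leaf, sheath+stem and dead-material
components by per-plot sampled fractions, and a fresh-matter (green) weight is
implied by a per-plot moisture fraction — so that the downstream field/lab
weighing arithmetic round-trips exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .layout import GenotypeClass, TrialLayout
from .traits import FieldSample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneticParams:
    """Population parameters of the simulated trial.

    Variances are on the kg/ha scale of TDMY. ``check_effects`` are fixed
    deviations for check genotypes (defaults to zero for every check);
    ``rep_effects`` are fixed replication deviations. Component-fraction and
    moisture parameters control the dry-matter decomposition and the implied
    green (fresh) weight per plot.
    """

    mu: float = 2000.0
    Vg: float = 44258.0
    Vb: float = 20000.0
    Ve: float = 100000.0
    rho_row: float = 0.3
    rho_col: float = 0.3
    check_effects: dict[str, float] = field(default_factory=dict)
    rep_effects: tuple[float, ...] = ()
    leaf_frac_mean: float = 0.55
    leaf_frac_sd: float = 0.05
    dead_frac_mean: float = 0.05
    dead_frac_sd: float = 0.02
    moisture_range: tuple[float, float] = (0.70, 0.78)
    sample_green_weight_range: tuple[float, float] = (300.0, 500.0)

    def validate(self) -> None:
        for name, v in (("Vg", self.Vg), ("Vb", self.Vb), ("Ve", self.Ve)):
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, r in (("rho_row", self.rho_row), ("rho_col", self.rho_col)):
            if not abs(r) < 1:
                raise ValueError(f"|{name}| must be < 1, got {r}")
        lo, hi = self.moisture_range
        if not (0 < lo <= hi < 1):
            raise ValueError(f"moisture_range must lie in (0, 1), got {self.moisture_range}")
        slo, shi = self.sample_green_weight_range
        if not (0 < slo <= shi):
            raise ValueError("sample_green_weight_range must be positive")


@dataclass(frozen=True)
class PlotTruth:
    """Ground-truth state of one simulated plot (yields in kg/ha, green matter in kg)."""

    plot_id: int
    true_tdmy: float
    true_ldmy: float
    true_ssdmy: float
    true_dmdmy: float
    true_green_matter: float
    family_effect: float
    block_effect: float
    residual: float


def ar1_matrix(rho: float, n: int) -> np.ndarray:
    """AR1 correlation matrix: entry (i, j) = rho^|i-j|."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _sample_ar1_field(rng: np.random.Generator, n_rows: int, n_cols: int,
                      rho_row: float, rho_col: float) -> np.ndarray:
    """Unit-variance matrix-normal draw with AR1 row and column correlation.

    Uses the Kronecker identity: if Z is iid N(0,1), L_r Z L_c' has covariance
    AR1(rho_row) (x) AR1(rho_col). Exact (Cholesky), cheap at field sizes.
    """
    L_r = np.linalg.cholesky(ar1_matrix(rho_row, n_rows))
    L_c = np.linalg.cholesky(ar1_matrix(rho_col, n_cols))
    Z = rng.standard_normal((n_rows, n_cols))
    return L_r @ Z @ L_c.T


def simulate_trial(layout: TrialLayout, params: GeneticParams = GeneticParams(),
                   seed: int = 0) -> list[PlotTruth]:
    """Draw one realization of the trial under the generative model.

    Deterministic for a fixed seed. Negative assembled yields are truncated to
    zero and the truncation count logged.
    """
    params.validate()
    layout.validate()
    rng = np.random.default_rng(seed)

    families = layout.family_ids
    fam_eff = dict(zip(families, rng.normal(0.0, np.sqrt(params.Vg), len(families))))
    block_keys = sorted({(p.rep, p.block) for p in layout.plots})
    blk_eff = dict(zip(block_keys, rng.normal(0.0, np.sqrt(params.Vb), len(block_keys))))
    resid_field = np.sqrt(params.Ve) * _sample_ar1_field(
        rng, layout.n_rows, layout.n_cols, params.rho_row, params.rho_col
    )

    rep_effects = params.rep_effects or (0.0,) * layout.n_reps
    if len(rep_effects) < layout.n_reps:
        raise ValueError("rep_effects shorter than number of replications")

    truths: list[PlotTruth] = []
    n_trunc = 0
    for p in layout.plots:
        g = (
            fam_eff[p.genotype_id]
            if p.genotype_class is GenotypeClass.FAMILY
            else params.check_effects.get(p.genotype_id, 0.0)
        )
        b = blk_eff[(p.rep, p.block)]
        e = resid_field[p.field_row - 1, p.field_col - 1]
        tdmy = params.mu + rep_effects[p.rep - 1] + g + b + e
        if tdmy < 0:
            tdmy = 0.0
            n_trunc += 1

        leaf = float(np.clip(rng.normal(params.leaf_frac_mean, params.leaf_frac_sd), 0.05, 0.95))
        dead = float(np.clip(rng.normal(params.dead_frac_mean, params.dead_frac_sd), 0.0, 1.0 - leaf))
        ldmy = leaf * tdmy
        dmdmy = dead * tdmy
        ssdmy = tdmy - ldmy - dmdmy  # exact additivity by construction

        moisture = rng.uniform(*params.moisture_range)
        dry_kg = tdmy * layout.plot_area_m2 / 10_000.0
        green_kg = dry_kg / (1.0 - moisture)

        truths.append(
            PlotTruth(
                plot_id=p.plot_id,
                true_tdmy=tdmy,
                true_ldmy=ldmy,
                true_ssdmy=ssdmy,
                true_dmdmy=dmdmy,
                true_green_matter=green_kg,
                family_effect=g if p.genotype_class is GenotypeClass.FAMILY else 0.0,
                block_effect=b,
                residual=e,
            )
        )
    if n_trunc:
        logger.info("simulate_trial: truncated %d negative yields to 0", n_trunc)
    return truths


def derive_field_samples(truths: list[PlotTruth], layout: TrialLayout,
                         params: GeneticParams = GeneticParams(),
                         seed: int = 0) -> list[FieldSample]:
    """Emit field/lab weighing records consistent with the simulated truth.

    The total green matter weight per plot (TGMW) is the truth's green matter;
    a sample green weight (SGW, grams) is drawn uniformly from
    ``params.sample_green_weight_range`` and the sample's component dry weights
    are set so that the standard yield arithmetic
    (``component_yields`` then ``yields_to_kg_ha``) recovers the true per-plot
    yields exactly (up to floating point).
    """
    rng = np.random.default_rng(seed)
    area = layout.plot_area_m2
    samples: list[FieldSample] = []
    for t in truths:
        tgmw = t.true_green_matter
        if tgmw <= 0.0:
            samples.append(FieldSample(t.plot_id, 0.0, 0.0, 0.0, 0.0, 0.0))
            continue
        sgw = rng.uniform(*params.sample_green_weight_range)
        # dry kg of each component on the plot scale
        d_leaf = t.true_ldmy * area / 10_000.0
        d_stem = t.true_ssdmy * area / 10_000.0
        d_dead = t.true_dmdmy * area / 10_000.0
        # sample dry weights (g): the sample is a proportional aliquot of the plot
        samples.append(
            FieldSample(
                plot_id=t.plot_id,
                TGMW=tgmw,
                SGW=sgw,
                LDMW=sgw * d_leaf / tgmw,
                SSDMW=sgw * d_stem / tgmw,
                DMDMW=sgw * d_dead / tgmw,
            )
        )
    return samples


def truths_to_dataframe(truths: list[PlotTruth]):
    import pandas as pd

    return pd.DataFrame([t.__dict__ for t in truths])
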