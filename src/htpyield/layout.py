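"""Field-trial layout: genotype entries, replications, incomplete blocks, grid coordinates.

The reference design is a resolvable incomplete-block (alpha-lattice-style)
trial: each replication contains every entry exactly once, partitioned into
equal-size blocks whose contents and order are randomized per replication.
The default mirrors a guineagrass progeny trial: 86 full-sib families, ten
sexual and ten apomictic genitors, and four commercial cultivar checks
(110 entries), three replications, 330 plots of 4.5 m2 each.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._grid import NUMBERINGS, index_to_rowcol


class GenotypeClass(str, enum.Enum):
    FAMILY = "family"
    GENITOR_SEXUAL = "genitor_sexual"
    GENITOR_APOMICTIC = "genitor_apomictic"
    CULTIVAR_CHECK = "cultivar_check"

    @property
    def is_check(self) -> bool:
        """Checks (genitors + cultivars) enter the mixed model as fixed effects."""
        return self is not GenotypeClass.FAMILY


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: position, replication/block membership and its genotype."""

    plot_id: int
    field_row: int  # 1-based
    field_col: int  # 1-based
    rep: int  # 1-based
    block: int  # 1-based, nested within rep
    genotype_id: str
    genotype_class: GenotypeClass


@dataclass(frozen=True)
class DesignConfig:
    """Parameters of the trial design (defaults give the 330-plot trial)."""

    n_families: int = 86
    n_genitors_sexual: int = 10
    n_genitors_apomictic: int = 10
    n_cultivar_checks: int = 4
    n_reps: int = 3
    blocks_per_rep: int = 11
    n_field_rows: int = 22
    n_field_cols: int = 15
    plot_area_m2: float = 4.5
    numbering: str = "row_major"

    @property
    def entries_per_rep(self) -> int:
        return (
            self.n_families
            + self.n_genitors_sexual
            + self.n_genitors_apomictic
            + self.n_cultivar_checks
        )

    @property
    def n_plots(self) -> int:
        return self.entries_per_rep * self.n_reps


@dataclass
class TrialLayout:
    plots: list[PlotRecord]
    n_rows: int
    n_cols: int
    n_reps: int
    blocks_per_rep: int
    plot_area_m2: float
    genotype_registry: dict[str, GenotypeClass] = field(default_factory=dict)
    numbering: str = "row_major"

    @property
    def n_plots(self) -> int:
        return len(self.plots)

    @property
    def family_ids(self) -> list[str]:
        return sorted(g for g, c in self.genotype_registry.items() if c is GenotypeClass.FAMILY)

    @property
    def check_ids(self) -> list[str]:
        return sorted(g for g, c in self.genotype_registry.items() if c is not GenotypeClass.FAMILY)

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        fam_per_rep: dict[tuple[int, str], int] = {}
        for p in self.plots:
            if not (1 <= p.field_row <= self.n_rows and 1 <= p.field_col <= self.n_cols):
                raise ValueError(f"plot {p.plot_id} outside the {self.n_rows}x{self.n_cols} grid")
            if not 1 <= p.block <= self.blocks_per_rep:
                raise ValueError(f"plot {p.plot_id} has block {p.block} out of range")
            pos = (p.field_row, p.field_col)
            if pos in seen:
                raise ValueError(f"grid cell {pos} occupied twice")
            seen.add(pos)
            if p.genotype_class is GenotypeClass.FAMILY:
                key = (p.rep, p.genotype_id)
                fam_per_rep[key] = fam_per_rep.get(key, 0) + 1
        bad = [k for k, v in fam_per_rep.items() if v != 1]
        if bad:
            raise ValueError(f"families appearing != once in a replication: {bad[:5]}")
        if self.plot_area_m2 <= 0:
            raise ValueError("plot_area_m2 must be positive")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "plot_id": [p.plot_id for p in self.plots],
                "field_row": [p.field_row for p in self.plots],
                "field_col": [p.field_col for p in self.plots],
                "rep": [p.rep for p in self.plots],
                "block": [p.block for p in self.plots],
                "genotype_id": [p.genotype_id for p in self.plots],
                "genotype_class": [p.genotype_class.value for p in self.plots],
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, plot_area_m2: float = 4.5,
                       numbering: str = "row_major") -> "TrialLayout":
        plots = [
            PlotRecord(
                plot_id=int(r.plot_id),
                field_row=int(r.field_row),
                field_col=int(r.field_col),
                rep=int(r.rep),
                block=int(r.block),
                genotype_id=str(r.genotype_id),
                genotype_class=GenotypeClass(r.genotype_class),
            )
            for r in df.itertuples()
        ]
        registry = {p.genotype_id: p.genotype_class for p in plots}
        layout = cls(
            plots=plots,
            n_rows=int(df.field_row.max()),
            n_cols=int(df.field_col.max()),
            n_reps=int(df.rep.max()),
            blocks_per_rep=int(df.block.max()),
            plot_area_m2=plot_area_m2,
            genotype_registry=registry,
            numbering=numbering,
        )
        layout.validate()
        return layout


def make_layout(config: DesignConfig = DesignConfig(), seed: int = 0) -> TrialLayout:
    """Build a randomized resolvable-block layout on a rectangular grid.

    Within each replication the entries are shuffled, chunked into
    ``blocks_per_rep`` equal blocks, and the block order shuffled again; plots
    are then laid on the grid in ``config.numbering`` order. Deterministic for
    a fixed seed.
    """
    entries = config.entries_per_rep
    if entries % config.blocks_per_rep != 0:
        raise ValueError(
            f"{entries} entries per rep not divisible into {config.blocks_per_rep} blocks"
        )
    if config.n_field_rows * config.n_field_cols < config.n_plots:
        raise ValueError(
            f"grid {config.n_field_rows}x{config.n_field_cols} too small for "
            f"{config.n_plots} plots"
        )
    if config.numbering not in NUMBERINGS:
        raise ValueError(f"unknown numbering {config.numbering!r}")

    registry: dict[str, GenotypeClass] = {}
    for i in range(config.n_families):
        registry[f"F{i + 1:03d}"] = GenotypeClass.FAMILY
    for i in range(config.n_genitors_sexual):
        registry[f"GS{i + 1:02d}"] = GenotypeClass.GENITOR_SEXUAL
    for i in range(config.n_genitors_apomictic):
        registry[f"GA{i + 1:02d}"] = GenotypeClass.GENITOR_APOMICTIC
    for i in range(config.n_cultivar_checks):
        registry[f"CHK{i + 1}"] = GenotypeClass.CULTIVAR_CHECK
    entry_ids = list(registry)

    rng = np.random.default_rng(seed)
    block_size = entries // config.blocks_per_rep
    plots: list[PlotRecord] = []
    k = 0
    for rep in range(1, config.n_reps + 1):
        order = list(rng.permutation(entry_ids))
        blocks = [order[b * block_size : (b + 1) * block_size] for b in range(config.blocks_per_rep)]
        block_order = rng.permutation(config.blocks_per_rep)
        for b_idx, b in enumerate(block_order, start=1):
            for gid in blocks[b]:
                row, col = index_to_rowcol(k, config.n_field_cols, config.numbering)
                plots.append(
                    PlotRecord(
                        plot_id=k + 1,
                        field_row=row + 1,
                        field_col=col + 1,
                        rep=rep,
                        block=b_idx,
                        genotype_id=gid,
                        genotype_class=registry[gid],
                    )
                )
                k += 1

    layout = TrialLayout(
        plots=plots,
        n_rows=config.n_field_rows,
        n_cols=config.n_field_cols,
        n_reps=config.n_reps,
        blocks_per_rep=config.blocks_per_rep,
        plot_area_m2=config.plot_area_m2,
        genotype_registry=registry,
        numbering=config.numbering,
    )
    layout.validate()
    return layout
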