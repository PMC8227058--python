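"""Dry-matter yield arithmetic from field and laboratory weights.

A harvested plot is weighed fresh in the field (TGMW, kg); a 300-500 g aliquot
(SGW, g) is separated into leaf blades, sheaths+stems and dead material, dried
(65 C, 72 h) and re-weighed (LDMW, SSDMW, DMDMW, g). Per-plot dry matter of
each component is the plot fresh weight scaled by the sample's dry:fresh
ratio, and per-plot yields are converted to kg/ha by the plot area.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

HA_M2 = 10_000.0

#: metadata of the harvest protocol; carried for documentation, not computation
HARVEST_HEIGHT_M = 0.2
DRYING = {"temperature_c": 65, "hours": 72}


@dataclass(frozen=True)
class FieldSample:
    """Field + lab weights of one plot. TGMW in kg, sample weights in grams."""

    plot_id: int
    TGMW: float
    SGW: float
    LDMW: float
    SSDMW: float
    DMDMW: float

    def validate(self) -> None:
        for name in ("TGMW", "SGW", "LDMW", "SSDMW", "DMDMW"):
            if getattr(self, name) < 0:
                raise ValueError(f"plot {self.plot_id}: {name} is negative")
        if self.TGMW > 0 and self.SGW <= 0:
            raise ValueError(f"plot {self.plot_id}: SGW must be positive when TGMW > 0")
        if self.LDMW + self.SSDMW + self.DMDMW > self.SGW * (1 + 1e-9):
            raise ValueError(f"plot {self.plot_id}: dry components exceed sample green weight")


@dataclass(frozen=True)
class PlotYield:
    """Per-plot dry matter (kg) and, once converted, kg/ha fields."""

    plot_id: int
    LDMY: float
    SSDMY: float
    DMDMY: float
    TDMY: float
    ldmy_ha: float | None = None
    tdmy_ha: float | None = None


def component_yields(s: FieldSample) -> PlotYield:
    """Per-plot component dry matter: yield = TGMW * (component dry weight / SGW).

    All sample weights must share one unit (grams here); the ratio is what
    matters. Output is in TGMW's unit (kg per plot).
    """
    s.validate()
    if s.TGMW == 0.0:
        return PlotYield(s.plot_id, 0.0, 0.0, 0.0, 0.0)
    if s.SGW == 0.0:
        raise ZeroDivisionError(f"plot {s.plot_id}: SGW = 0 with TGMW > 0")
    ldmy = s.TGMW * s.LDMW / s.SGW
    ssdmy = s.TGMW * s.SSDMW / s.SGW
    dmdmy = s.TGMW * s.DMDMW / s.SGW
    return PlotYield(s.plot_id, ldmy, ssdmy, dmdmy, ldmy + ssdmy + dmdmy)


def yields_to_kg_ha(y: PlotYield, plot_area_m2: float) -> PlotYield:
    """Fill the kg/ha fields: ha value = plot kg * 10000 / area."""
    if plot_area_m2 <= 0:
        raise ValueError(f"plot_area_m2 must be positive, got {plot_area_m2}")
    f = HA_M2 / plot_area_m2
    return replace(y, ldmy_ha=y.LDMY * f, tdmy_ha=y.TDMY * f)


def samples_to_dataframe(samples: list[FieldSample]) -> pd.DataFrame:
    df = pd.DataFrame([s.__dict__ for s in samples])
    return df.rename(
        columns={"TGMW": "tgmw_kg", "SGW": "sgw_g", "LDMW": "ldmw_g",
                 "SSDMW": "ssdmw_g", "DMDMW": "dmdmw_g"}
    )


def samples_from_dataframe(df: pd.DataFrame) -> list[FieldSample]:
    return [
        FieldSample(int(r.plot_id), float(r.tgmw_kg), float(r.sgw_g),
                    float(r.ldmw_g), float(r.ssdmw_g), float(r.dmdmw_g))
        for r in df.itertuples()
    ]


def yields_to_dataframe(yields: list[PlotYield]) -> pd.DataFrame:
    df = pd.DataFrame([y.__dict__ for y in yields])
    return df.rename(
        columns={"LDMY": "ldmy_kg", "SSDMY": "ssdmy_kg", "DMDMY": "dmdmy_kg",
                 "TDMY": "tdmy_kg", "ldmy_ha": "ldmy_kg_ha", "tdmy_ha": "tdmy_kg_ha"}
    )


def plot_yields(samples: list[FieldSample], plot_area_m2: float) -> pd.DataFrame:
    """Convenience: component yields + ha conversion for a whole trial."""
    out = [yields_to_kg_ha(component_yields(s), plot_area_m2) for s in samples]
    return yields_to_dataframe(out)
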