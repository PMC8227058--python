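"""Selection intensity and direct/correlated response to selection.

Truncation selection on a normal trait: selecting the top proportion p gives a
standardized selection intensity i = phi(z_p)/p, with z_p the upper-p quantile
of the standard normal and phi its density. Direct response for the real trait
is DR = i * h_real * v, and the correlated response from selecting on a
secondary (image-derived, HTP) trait is CR = i * h_HTP * r * v, where h is the
square root of broad-sense heritability H, r the (approximate) genetic
correlation between HTP and real trait, and v the square root of the real
trait's family variance Vg. CR/DR measures indirect-selection efficiency.

Reported response tables conventionally use i rounded to two decimals
(1.76, 2.06, 2.67 for p = 10%, 5%, 1%); internals keep full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd
from scipy import stats


def selection_intensity(p: float) -> float:
    """Standardized selection differential for truncating the top proportion p."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"selected proportion must be in (0, 1), got {p}")
    z = stats.norm.ppf(1.0 - p)
    return float(stats.norm.pdf(z) / p)


def printed_intensity(i: float, decimals: int = 2) -> float:
    """Selection intensity at the reporting precision.

    Classical tables list i to three decimals (1.755, 2.063, 2.665 for
    p = 10%, 5%, 1%) and reports round those half-up — giving the familiar
    1.76, 2.06, 2.67. Reproduced here: half-up to ``decimals + 1`` places,
    then half-up to ``decimals``.
    """
    d = Decimal(repr(i)).quantize(Decimal(1).scaleb(-(decimals + 1)), rounding=ROUND_HALF_UP)
    return float(d.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP))


def direct_response(i: float, H_real: float, Vg_real: float) -> float:
    """DR = i * sqrt(H_real) * sqrt(Vg_real), in trait units (kg/ha here)."""
    if not 0.0 <= H_real <= 1.0:
        raise ValueError(f"H_real must be in [0, 1] (negative H has no square root), got {H_real}")
    if Vg_real < 0:
        raise ValueError(f"Vg_real must be >= 0, got {Vg_real}")
    return i * math.sqrt(H_real) * math.sqrt(Vg_real)


def correlated_response(i: float, H_htp: float, r: float, Vg_real: float) -> float:
    """CR = i * sqrt(H_htp) * r * sqrt(Vg_real); selection on the HTP trait."""
    if not 0.0 <= H_htp <= 1.0:
        raise ValueError(f"H_htp must be in [0, 1] (negative H has no square root), got {H_htp}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"genetic correlation must be in [-1, 1], got {r}")
    if Vg_real < 0:
        raise ValueError(f"Vg_real must be >= 0, got {Vg_real}")
    return i * math.sqrt(H_htp) * r * math.sqrt(Vg_real)


@dataclass(frozen=True)
class SelectionScenario:
    """One selection scenario: proportion selected and (optionally) a printed i.

    If ``i`` is None it is computed from ``p`` and rounded to ``i_decimals``
    (the reporting convention); pass ``i_decimals=None`` for full precision.
    n_plots / n_families are documentation metadata — genetic parameters are
    held fixed across scenario sizes.
    """

    p: float
    i: float | None = None
    label: str = ""
    n_plots: int | None = None
    n_families: int | None = None
    i_decimals: int | None = 2

    def intensity(self) -> float:
        if self.i is not None:
            if self.i <= 0:
                raise ValueError("selection intensity must be positive")
            return self.i
        i = selection_intensity(self.p)
        return printed_intensity(i, self.i_decimals) if self.i_decimals is not None else i


DEFAULT_SCENARIOS = (
    SelectionScenario(p=0.10, label="SI = 10%", n_plots=330, n_families=86),
    SelectionScenario(p=0.05, label="SI = 5%", n_plots=660, n_families=172),
    SelectionScenario(p=0.01, label="SI = 1%", n_plots=3300, n_families=860),
)


@dataclass
class SelectionTable:
    """Direct and correlated responses per scenario for one trait."""

    trait: str
    dr: float  # at the baseline (first) scenario's intensity
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def printed(self) -> pd.DataFrame:
        """Responses at the printed rounding: integer kg/ha, 2-decimal ratios."""
        df = self.to_dataframe().copy()
        df["DR"] = df["DR"].round().astype("Int64")
        df["CR"] = df["CR"].round().astype("Int64")
        df["CR/DR"] = df["CR/DR"].round(2)
        return df


def scenario_table(real, htp, scenarios=DEFAULT_SCENARIOS, trait: str | None = None) -> SelectionTable:
    """Build the scenario table: DR at the baseline intensity, CR per scenario.

    ``real`` and ``htp`` are genetic summaries (``GeneticSummary`` or anything
    with H, Vg and — for htp — r attributes) of the same trait. CR/DR ratios
    are kept at full precision; use :meth:`SelectionTable.printed` for the
    reporting convention.
    """
    for name, s in (("real", real), ("htp", htp)):
        for attr in ("H",) + (("r",) if name == "htp" else ()):
            v = getattr(s, attr, None)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise ValueError(f"{name} summary is missing {attr}")
    if not scenarios:
        raise ValueError("no scenarios given")
    trait = trait or getattr(real, "trait", "trait")

    baseline_i = scenarios[0].intensity()
    dr = direct_response(baseline_i, real.H, real.Vg)
    table = SelectionTable(trait=trait, dr=dr)
    for sc in scenarios:
        i = sc.intensity()
        cr = correlated_response(i, htp.H, htp.r, real.Vg)
        table.rows.append(
            {
                "label": sc.label or f"SI = {sc.p:.0%}",
                "p": sc.p,
                "i": i,
                "n_plots": sc.n_plots,
                "n_families": sc.n_families,
                "DR": dr,
                "CR": cr,
                "CR/DR": cr / dr,
            }
        )
    return table
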