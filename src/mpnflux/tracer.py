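"""Radiotracer flux calculus for 14C-labelled substrate incubations.

Converts liquid-scintillation counts (dpm, background/quench corrected) to
per-cell carbon fluxes.  The chain is:

    dpm  --/ (SA_eff * 2.22e12 dpm Ci^-1) -->  mol substrate C
         --/ (cells * volume)             -->  mol cell^-1
         --/ duration                     -->  mol cell^-1 h^-1

where SA_eff is the effective specific activity of the substrate pool after
isotope dilution by unlabelled carrier: rates are expressed in moles of
total (labelled + unlabelled) substrate, which is what dividing the added
activity by the total substrate concentration achieves.  CO2-trap samples
are treated identically — the trapped dpm are simply the numerator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .units import DPM_PER_CI, MOL_PER_ZMOL, ZMOL_PER_AMOL

__all__ = [
    "TracerIncubation",
    "FluxEstimate",
    "tracer_molarity",
    "effective_specific_activity",
    "dpm_to_mol",
    "mol_to_dpm",
    "cell_specific_rate",
    "daily_rate",
    "read_incubations_csv",
    "estimate_fluxes",
]

CONDITIONS = ("light", "dark", "co2_trap")


@dataclass(frozen=True)
class TracerIncubation:
    """One 14C incubation record.

    activity_added: added radioactivity, uCi ml^-1.
    sa_stock: specific activity of the radiotracer stock, Ci mol^-1.
    carrier_conc: unlabelled substrate carried in the medium, uM.
    dpm: background-corrected disintegrations min^-1 recovered on the filter
         (or in the CO2 trap).
    volume: incubation volume, ml.  cell_density: cells ml^-1.
    duration: h.  condition: 'light' | 'dark' | 'co2_trap'.
    """

    activity_added: float
    sa_stock: float
    carrier_conc: float
    dpm: float
    volume: float
    cell_density: float
    duration: float
    condition: str = "light"

    def __post_init__(self) -> None:
        if self.dpm < 0:
            raise ValueError("dpm must be non-negative")
        if self.sa_stock <= 0:
            raise ValueError("stock specific activity must be positive")
        if self.duration <= 0:
            raise ValueError("incubation duration must be positive")
        if self.carrier_conc < 0:
            raise ValueError("carrier concentration cannot be negative")
        if self.volume <= 0:
            raise ValueError("volume must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")


@dataclass(frozen=True)
class FluxEstimate:
    rate_zmol_per_cell_h: float
    condition: str

    @property
    def rate_amol_per_cell_day(self) -> float:
        """Same rate held for 24 h, in amol cell^-1 d^-1 (1 amol = 10^3 zmol)."""
        return self.rate_zmol_per_cell_h * 24.0 / ZMOL_PER_AMOL


def tracer_molarity(activity: float, sa: float) -> float:
    """Molar concentration (uM) of radiotracer added at `activity` uCi ml^-1.

    activity [uCi ml^-1] x 1e-6 Ci/uCi x 1e3 ml/L / sa [Ci mol^-1]
    = activity/sa x 1e-3 mol L^-1 x 1e6 uM/M = activity/sa x 1e3 uM.
    """
    if sa <= 0:
        raise ValueError("specific activity must be positive")
    if activity < 0:
        raise ValueError("activity cannot be negative")
    return activity / sa * 1e3


def effective_specific_activity(activity: float, sa_stock: float, carrier: float) -> float:
    """Specific activity of the total substrate pool (Ci mol^-1) after dilution.

    The added activity is divided by the total substrate concentration
    (hot tracer + cold carrier), so downstream rates count moles of total
    substrate.  With zero carrier this returns sa_stock exactly.
    """
    if carrier < 0:
        raise ValueError("carrier concentration cannot be negative")
    if activity < 0:
        raise ValueError("activity cannot be negative")
    hot_um = tracer_molarity(activity, sa_stock)
    total_um = hot_um + carrier
    if total_um == 0:
        raise ValueError("total substrate concentration is zero")
    # uCi ml^-1 over uM: (activity*1e-3 Ci L^-1) / (total*1e-6 mol L^-1)
    return activity * 1e3 / total_um


def dpm_to_mol(dpm: float, sa: float) -> float:
    """Moles of substrate represented by `dpm` at specific activity `sa` (Ci mol^-1)."""
    if sa <= 0:
        raise ValueError("specific activity must be positive")
    return dpm / (sa * DPM_PER_CI)


def mol_to_dpm(mol: float, sa: float) -> float:
    """Inverse of dpm_to_mol."""
    if sa <= 0:
        raise ValueError("specific activity must be positive")
    return mol * sa * DPM_PER_CI


def cell_specific_rate(inc: TracerIncubation) -> FluxEstimate:
    """Per-cell substrate-carbon flux (zmol C cell^-1 h^-1) from one incubation."""
    if inc.cell_density <= 0:
        raise ValueError("cell density must be positive to normalise the rate")
    sa_eff = effective_specific_activity(inc.activity_added, inc.sa_stock, inc.carrier_conc)
    mol = dpm_to_mol(inc.dpm, sa_eff)
    rate_mol = mol / (inc.cell_density * inc.volume) / inc.duration
    return FluxEstimate(rate_zmol_per_cell_h=rate_mol / MOL_PER_ZMOL,
                        condition=inc.condition)


def daily_rate(light: float, dark: float, light_h: float = 12.0) -> float:
    """Compose hourly light/dark rates (zmol cell^-1 h^-1) into amol cell^-1 d^-1.

    The photoperiod defaults to 12 h light : 12 h dark.  A directly measured
    24-h rate may of course be used instead of this composition.
    """
    if not 0.0 <= light_h <= 24.0:
        raise ValueError("light hours must be within 0-24")
    return (light * light_h + dark * (24.0 - light_h)) / ZMOL_PER_AMOL


# ---------------------------------------------------------------- CSV I/O

INCUBATION_COLUMNS = ("condition", "dpm", "activity_uCi_ml", "sa_Ci_mol",
                      "carrier_uM", "volume_ml", "cells_per_ml", "duration_h")


def read_incubations_csv(path) -> list[TracerIncubation]:
    df = pd.read_csv(path)
    missing = set(INCUBATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"incubation CSV missing columns: {sorted(missing)}")
    return [
        TracerIncubation(
            activity_added=row.activity_uCi_ml, sa_stock=row.sa_Ci_mol,
            carrier_conc=row.carrier_uM, dpm=row.dpm, volume=row.volume_ml,
            cell_density=row.cells_per_ml, duration=row.duration_h,
            condition=row.condition,
        )
        for row in df.itertuples(index=False)
    ]


def estimate_fluxes(incubations: Iterable[TracerIncubation]) -> pd.DataFrame:
    """Tabulate per-incubation flux estimates."""
    rows = []
    for inc in incubations:
        est = cell_specific_rate(inc)
        rows.append({"condition": est.condition,
                     "rate_zmol_per_cell_h": est.rate_zmol_per_cell_h,
                     "rate_amol_per_cell_day": est.rate_amol_per_cell_day})
    return pd.DataFrame(rows, columns=["condition", "rate_zmol_per_cell_h",
                                       "rate_amol_per_cell_day"])
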