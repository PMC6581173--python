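"""Macromolecular fractionation accounting, TLC spot assignment, calibration.

Radiolabelled cell pellets are sequentially extracted into acid-soluble
metabolites, lipids, RNA, DNA and protein; each fraction's dpm is expressed
as a percentage of the dpm in intact (unfractionated) cell pellets, so the
percentages need not sum to 100 — the recovery is reported, never forced.

Also here: the brucite (Mg(OH)2) coprecipitation split of the acid-soluble
pool, nearest-standard assignment of 2-D TLC spots to nucleotide/nucleoside
standards, and a generic linear signal-vs-amount calibration (used for both
the colorimetric formate assay and molybdenum-blue phosphorus chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FRACTIONS",
    "PURINE_COMPOUNDS",
    "FractionationProfile",
    "TlcSpot",
    "SpotAssignment",
    "CalibrationCurve",
    "fraction_percentages",
    "brucite_fraction",
    "assign_tlc_spots",
    "purine_label_fraction",
    "calibrate_linear",
    "invert_calibration",
    "read_fractionation_csv",
]

#: Sequential extraction order: cold-TCA metabolites, ethanol lipids,
#: NaOH-hydrolysed RNA, hot-TCA DNA, residual protein.
FRACTIONS = ("metabolite", "lipid", "RNA", "DNA", "protein")

#: Purine species among common ribonucleotide / deoxynucleoside standards.
PURINE_COMPOUNDS = frozenset({"AMP", "GMP", "dA", "dG",
                              "deoxyadenosine", "deoxyguanosine"})


@dataclass(frozen=True)
class FractionationProfile:
    """dpm per macromolecular fraction plus whole-pellet dpm, one replicate."""

    replicate: str
    dpm: Mapping[str, float]
    pellet_total_dpm: float

    def __post_init__(self) -> None:
        if self.pellet_total_dpm <= 0:
            raise ValueError("pellet total dpm must be positive")
        if any(v < 0 for v in self.dpm.values()):
            raise ValueError("fraction dpm cannot be negative")


@dataclass(frozen=True)
class TlcSpot:
    """One excised TLC spot: retention factors in two solvent dimensions + dpm."""

    spot_id: str
    rf1: float
    rf2: float
    dpm: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rf1 <= 1.0 and 0.0 <= self.rf2 <= 1.0):
            raise ValueError("retention factors must lie in [0, 1]")
        if self.dpm < 0:
            raise ValueError("dpm cannot be negative")


@dataclass(frozen=True)
class SpotAssignment:
    spot: TlcSpot
    compound: str | None      # None if beyond the distance cutoff
    distance: float
    tie: bool = False


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal = intercept + slope * amount calibration."""

    slope: float
    intercept: float
    r2: float
    n_standards: int

    def predict(self, amount) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(amount, dtype=float)


def fraction_percentages(profile: FractionationProfile) -> tuple[dict[str, float], float]:
    """Each fraction's dpm as % of the intact-pellet dpm, plus the recovery.

    Recovery = (sum of fraction dpm) / pellet dpm; values above 1 indicate
    counting or carrier artefacts and are reported as-is.
    """
    total = profile.pellet_total_dpm
    pct = {frac: dpm / total * 100.0 for frac, dpm in profile.dpm.items()}
    recovery = sum(profile.dpm.values()) / total
    return pct, recovery


def brucite_fraction(ppt_dpm: float, supernatant_dpm: float) -> float:
    """Share of acid-soluble label coprecipitating with authigenic Mg(OH)2."""
    if ppt_dpm < 0 or supernatant_dpm < 0:
        raise ValueError("dpm cannot be negative")
    total = ppt_dpm + supernatant_dpm
    if total == 0:
        raise ValueError("no radioactivity recovered in either pool")
    return ppt_dpm / total


def assign_tlc_spots(
    spots: Iterable[TlcSpot],
    standards: Mapping[str, tuple[float, float]],
    cutoff: float = 0.1,
) -> tuple[dict[str, float], list[SpotAssignment]]:
    """Assign each spot to the nearest standard in (rf1, rf2) space.

    Distance is Euclidean; exact ties go to the lexicographically smaller
    compound name and are flagged.  Spots farther than `cutoff` from every
    standard stay unassigned.  Returns (dpm totals per compound, per-spot
    assignments); unassigned dpm are totalled under the key '_unassigned'.
    The default cutoff of 0.1 Rf units corresponds to ~1 cm spots on a
    10 cm sheet.
    """
    if not standards:
        raise ValueError("at least one standard is required")
    names = sorted(standards)
    coords = np.array([standards[n] for n in names], dtype=float)

    totals: dict[str, float] = {n: 0.0 for n in names}
    totals["_unassigned"] = 0.0
    assignments: list[SpotAssignment] = []
    for spot in spots:
        d = np.hypot(coords[:, 0] - spot.rf1, coords[:, 1] - spot.rf2)
        best = int(np.argmin(d))          # argmin takes the first == lexicographic
        dist = float(d[best])
        tie = bool(np.sum(d == dist) > 1)
        if dist > cutoff:
            totals["_unassigned"] += spot.dpm
            assignments.append(SpotAssignment(spot, None, dist, tie))
        else:
            totals[names[best]] += spot.dpm
            assignments.append(SpotAssignment(spot, names[best], dist, tie))
    return totals, assignments


def purine_label_fraction(
    dpm_by_compound: Mapping[str, float],
    purines: frozenset[str] | set[str] = PURINE_COMPOUNDS,
) -> float:
    """Fraction of assigned radiolabel found in purine species."""
    total = sum(v for k, v in dpm_by_compound.items() if not k.startswith("_"))
    if total <= 0:
        raise ValueError("no assigned radioactivity")
    purine = sum(v for k, v in dpm_by_compound.items() if k in purines)
    return purine / total


def calibrate_linear(standards: Sequence[tuple[float, float]]) -> CalibrationCurve:
    """Ordinary least-squares line through (amount, signal) standards."""
    if len(standards) < 3:
        raise ValueError("calibration requires at least 3 standards")
    amounts = np.asarray([s[0] for s in standards], dtype=float)
    signals = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(amounts) == 0:
        raise ValueError("standards must span a range of amounts")
    res = stats.linregress(amounts, signals)
    return CalibrationCurve(slope=float(res.slope), intercept=float(res.intercept),
                            r2=float(res.rvalue ** 2), n_standards=len(standards))


def invert_calibration(curve: CalibrationCurve, signal) -> tuple[np.ndarray, np.ndarray]:
    """Invert signals to amounts: (signal - intercept) / slope.

    Negative inverted amounts are floored at zero; returns (amounts,
    clipped mask) so the flooring is never silent.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; inversion undefined")
    raw = (np.asarray(signal, dtype=float) - curve.intercept) / curve.slope
    clipped = raw < 0
    return np.where(clipped, 0.0, raw), clipped


# ---------------------------------------------------------------- CSV I/O

def read_fractionation_csv(path) -> list[FractionationProfile]:
    """Columns: replicate, fraction, dpm, pellet_total_dpm (repeated per replicate)."""
    df = pd.read_csv(path)
    required = {"replicate", "fraction", "dpm", "pellet_total_dpm"}
    if missing := required - set(df.columns):
        raise ValueError(f"fractionation CSV missing columns: {sorted(missing)}")
    profiles = []
    for rep, grp in df.groupby("replicate", sort=True):
        totals = grp["pellet_total_dpm"].unique()
        if len(totals) != 1:
            raise ValueError(f"replicate {rep!r} has inconsistent pellet totals")
        profiles.append(FractionationProfile(
            replicate=str(rep),
            dpm=dict(zip(grp["fraction"], grp["dpm"].astype(float))),
            pellet_total_dpm=float(totals[0]),
        ))
    return profiles
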