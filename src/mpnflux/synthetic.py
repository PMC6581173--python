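"""Synthetic wet-lab data with known ground truth for every analysis stage.

No raw replicate-level measurements are deposited for this study system, so
the generator emulates the five input streams — growth curves, radiotracer
incubations, macromolecular fractionation profiles, formate assay plates,
and the genome-survey alignment table — from a configuration whose defaults
are the study's headline values (growth rates 0.18-0.42 d^-1, yield
6e8 cells ml^-1, per-cell MPn-C rates 250/89 zmol h^-1, P quota
20 amol cell^-1, per-cell formate 48/27 amol, fractionation split
~42/1.5/41/19/0.5%).  Every stream is seeded and byte-reproducible;
zero-noise configurations make the downstream estimators exact, which is
the backbone of the parameter-recovery test suite.

Noise models (the study reports only means +/- SDs, so these are declared
conventions): multiplicative lognormal on cell densities (counts are
positive and CV-stable), Poisson on scintillation dpm (counting
statistics, quench correction assumed already applied), multinomial on
fraction dpm, Gaussian on assay absorbances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .growth import GrowthCurve, logistic_density
from .tracer import TracerIncubation, effective_specific_activity, mol_to_dpm
from .fractionation import FRACTIONS, FractionationProfile
from .units import MOL_PER_ZMOL, ZMOL_PER_AMOL

__all__ = [
    "GrowthParams",
    "SimConfig",
    "gen_growth_curves",
    "gen_tracer_incubations",
    "gen_fractionation_profile",
    "gen_formate_assay",
    "gen_survey_table",
    "write_dataset",
]

#: Extraction categories for the multinomial split; 'residual' is label that
#: never appears in a recovered fraction (losses during extraction).
SIM_FRACTIONS = FRACTIONS + ("residual",)

# fixed substream indices so streams stay decoupled under one global seed
_STREAMS = {"growth": 0, "tracer": 1, "fractionation": 2, "assay": 3, "survey": 4}


@dataclass(frozen=True)
class GrowthParams:
    """Logistic parameters for one P substrate."""

    mu: float       # d^-1
    K: float        # cells ml^-1
    N0: float       # cells ml^-1

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("growth rate cannot be negative")
        if not (self.K > self.N0 > 0):
            raise ValueError("need K > N0 > 0")


def _default_growth() -> dict[str, GrowthParams]:
    # headline substrate-specific rates; Pi/HMPn/MPn yields comparable,
    # phosphite roughly half
    return {
        "Pi": GrowthParams(mu=0.42, K=6e8, N0=1e6),
        "phosphite": GrowthParams(mu=0.18, K=3e8, N0=1e6),
        "MPn": GrowthParams(mu=0.35, K=6e8, N0=1e6),
        "HMPn": GrowthParams(mu=0.39, K=6e8, N0=1e6),
    }


def _default_fraction_props() -> dict[str, float]:
    # measured percentages 42/1.5/41/19/0.5 sum to 104%; the simulated
    # label split must be a simplex, so they are normalised with zero residual
    raw = {"metabolite": 42.0, "lipid": 1.5, "RNA": 41.0, "DNA": 19.0,
           "protein": 0.5, "residual": 0.0}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def _default_formate() -> dict[str, float]:
    return {"Pi": 27.0, "phosphite": 27.0, "MPn": 48.0, "HMPn": 48.0}


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters for all synthetic data streams.

    Units: growth rates d^-1, densities cells ml^-1, per-cell carbon rates
    zmol C cell^-1 h^-1, quotas and formate inventories amol cell^-1,
    calibration slope absorbance per nmol.
    """

    growth: Mapping[str, GrowthParams] = field(default_factory=_default_growth)
    noise_cv: float = 0.05
    true_cell_rate_light: float = 250.0
    true_cell_rate_dark: float = 89.0
    true_co2_rate_day: float = 0.09      # amol C cell^-1 d^-1
    quota_P: float = 20.0
    formate_per_cell: Mapping[str, float] = field(default_factory=_default_formate)
    fraction_props: Mapping[str, float] = field(default_factory=_default_fraction_props)
    calib_slope: float = 0.05            # absorbance / nmol
    calib_intercept: float = 0.01        # absorbance
    assay_noise_sd: float = 0.0          # absorbance
    well_volume_ul: float = 50.0
    photoperiod_light_h: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV cannot be negative")
        if min(self.true_cell_rate_light, self.true_cell_rate_dark,
               self.true_co2_rate_day, self.quota_P) < 0:
            raise ValueError("rates and quotas cannot be negative")
        props = dict(self.fraction_props)
        if set(props) != set(SIM_FRACTIONS):
            raise ValueError(f"fraction proportions must cover {SIM_FRACTIONS}")
        if any(v < 0 for v in props.values()):
            raise ValueError("fraction proportions cannot be negative")
        if abs(sum(props.values()) - 1.0) > 1e-12:
            raise ValueError("fraction proportions must sum to 1")
        if self.calib_slope <= 0:
            raise ValueError("calibration slope must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        """Deterministic per-stream generator derived from the global seed."""
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAMS[stream],)))


# ------------------------------------------------------------- growth curves

def gen_growth_curves(
    cfg: SimConfig,
    n_rep: int = 3,
    sampling: Sequence[float] = tuple(range(0, 22)),
    substrates: Sequence[str] | None = None,
    rng: np.random.Generator | None = None,
) -> list[GrowthCurve]:
    """Logistic growth curves with multiplicative lognormal density noise.

    The lognormal factor has mean 1 and coefficient of variation
    `cfg.noise_cv`, so noisy densities are unbiased around the model curve.
    """
    t = np.asarray(sampling, dtype=float)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("sampling times must be strictly increasing")
    if n_rep < 1:
        raise ValueError("need at least one replicate")
    rng = rng if rng is not None else cfg.rng("growth")
    cv = cfg.noise_cv
    sigma = np.sqrt(np.log1p(cv ** 2))
    curves = []
    for substrate in (substrates or sorted(cfg.growth)):
        p = cfg.growth[substrate]
        clean = logistic_density(t, p.mu, p.K, p.N0)
        for rep in range(1, n_rep + 1):
            if cv == 0:
                dens = clean.copy()
            else:
                factor = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma, size=t.size)
                dens = clean * factor
            curves.append(GrowthCurve(substrate=substrate, replicate=f"r{rep}",
                                      time=t.copy(), density=dens))
    return curves


# -------------------------------------------------------- tracer incubations

def expected_dpm(rate_zmol_h: float, cell_density: float, volume_ml: float,
                 duration_h: float, sa_eff: float) -> float:
    """Forward model: dpm accumulated by a constant per-cell flux."""
    mol = rate_zmol_h * MOL_PER_ZMOL * cell_density * volume_ml * duration_h
    return mol_to_dpm(mol, sa_eff)


def gen_tracer_incubations(
    cfg: SimConfig,
    cell_density: float = 1e8,
    activity_added: float = 0.1,
    sa_stock: float = 59.0,
    carrier: float = 0.0,
    duration_h: float = 12.0,
    volume_ml: float = 30.0,
    n_rep: int = 3,
    conditions: Sequence[str] = ("light", "dark", "co2_trap"),
    poisson_noise: bool = True,
    rng: np.random.Generator | None = None,
) -> list[TracerIncubation]:
    """Simulate 14C incubations; realized dpm ~ Poisson(expected dpm).

    Light and dark incubations run `duration_h` under their respective
    hourly rates; CO2-trap incubations span a full day, with light/dark
    hours weighted by the configured photoperiod (the daily CO2 rate is
    spread uniformly over the photoperiod-weighted day).
    """
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    if activity_added < 0:
        raise ValueError("activity cannot be negative")
    rates = {"light": cfg.true_cell_rate_light, "dark": cfg.true_cell_rate_dark,
             "co2_trap": cfg.true_co2_rate_day * ZMOL_PER_AMOL / 24.0}
    if cell_density <= 0 and any(rates[c] > 0 for c in conditions):
        raise ValueError("zero cells cannot produce a nonzero flux")
    rng = rng if rng is not None else cfg.rng("tracer")
    sa_eff = effective_specific_activity(activity_added, sa_stock, carrier)
    out = []
    for condition in conditions:
        dur = 24.0 if condition == "co2_trap" else duration_h
        exp = expected_dpm(rates[condition], cell_density, volume_ml, dur, sa_eff)
        for _ in range(n_rep):
            dpm = float(rng.poisson(exp)) if poisson_noise else exp
            out.append(TracerIncubation(
                activity_added=activity_added, sa_stock=sa_stock,
                carrier_conc=carrier, dpm=dpm, volume=volume_ml,
                cell_density=cell_density, duration=dur, condition=condition))
    return out


# ------------------------------------------------------------- fractionation

def gen_fractionation_profile(
    cfg: SimConfig,
    total_dpm: int = 100_000,
    replicate: str = "r1",
    rng: np.random.Generator | None = None,
) -> FractionationProfile:
    """Multinomial split of the pellet label across extraction fractions.

    Counts falling in the 'residual' category are label lost during
    extraction: they appear in the pellet total but in no recovered
    fraction, so downstream recovery is <= 100%.
    """
    if total_dpm <= 0:
        raise ValueError("total dpm must be positive")
    rng = rng if rng is not None else cfg.rng("fractionation")
    probs = np.array([cfg.fraction_props[f] for f in SIM_FRACTIONS], dtype=float)
    counts = rng.multinomial(int(total_dpm), probs)
    dpm = {f: float(c) for f, c in zip(SIM_FRACTIONS, counts) if f != "residual"}
    return FractionationProfile(replicate=replicate, dpm=dpm,
                                pellet_total_dpm=float(total_dpm))


# -------------------------------------------------------------- formate assay

def formate_nmol_per_well(formate_amol_per_cell: float, cell_density: float,
                          well_volume_ul: float = 50.0) -> float:
    """Forward arithmetic: per-cell inventory -> nmol formate in one assay well."""
    mol_per_ml = formate_amol_per_cell * 1e-18 * cell_density
    return mol_per_ml * (well_volume_ul / 1000.0) * 1e9


def gen_formate_assay(
    cfg: SimConfig,
    cell_yields: Mapping[str, float] | None = None,
    n_rep: int = 3,
    standard_nmol: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0),
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Colorimetric formate assay plate: calibration standards plus samples.

    Standards span 0-10 nmol per well; sample wells hold the supernatant
    formate of each culture (per-cell inventory x cell yield x well volume).
    Absorbance = intercept + slope * nmol + Gaussian noise.
    Columns: role, substrate, replicate, amount_nmol (standards only),
    absorbance.
    """
    rng = rng if rng is not None else cfg.rng("assay")
    yields = dict(cell_yields) if cell_yields is not None else {
        s: p.K for s, p in cfg.growth.items()}
    rows = []

    def absorb(nmol: float) -> float:
        a = cfg.calib_intercept + cfg.calib_slope * nmol
        if cfg.assay_noise_sd > 0:
            a += rng.normal(0.0, cfg.assay_noise_sd)
        return a

    for amount in standard_nmol:
        for rep in range(1, n_rep + 1):
            rows.append({"role": "standard", "substrate": "",
                         "replicate": f"r{rep}", "amount_nmol": amount,
                         "absorbance": absorb(amount)})
    for substrate in sorted(yields):
        nmol = formate_nmol_per_well(cfg.formate_per_cell[substrate],
                                     yields[substrate], cfg.well_volume_ul)
        for rep in range(1, n_rep + 1):
            rows.append({"role": "sample", "substrate": substrate,
                         "replicate": f"r{rep}", "amount_nmol": np.nan,
                         "absorbance": absorb(nmol)})
    return pd.DataFrame(rows)


# ------------------------------------------------------------- genome survey

def gen_survey_table(
    n_by_ocean: Mapping[str, int],
    presence_prob_by_ocean: Mapping[str, float],
    identity_when_present: tuple[float, float] = (97.5, 100.0),
    identity_when_absent: tuple[float, float] = (30.0, 90.0),
    absent_hit_prob: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random genome-survey metadata plus a matching alignment table.

    Present genomes carry best hits to both reference proteins with
    identities drawn in `identity_when_present` (above the screen
    threshold); absent genomes either produce no alignment row at all or a
    sub-threshold hit.  Returns (metadata, alignments) in the schemas the
    presence screen reads.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                       spawn_key=(_STREAMS["survey"],)))
    meta_rows, aln_rows = [], []
    for ocean in sorted(n_by_ocean):
        n = n_by_ocean[ocean]
        p = presence_prob_by_ocean[ocean]
        if not 0.0 <= p <= 1.0:
            raise ValueError("presence probability must lie in [0, 1]")
        present = rng.random(n) < p
        for i in range(n):
            gid = f"{ocean}_{i:04d}"
            meta_rows.append({"genome_id": gid, "clade": "HLII",
                              "depth_m": float(rng.integers(5, 120)),
                              "latitude": 0.0, "longitude": 0.0, "ocean": ocean,
                              "truth_present": bool(present[i])})
            for prot in ("PhnY", "PhnZ"):
                if present[i]:
                    ident = rng.uniform(*identity_when_present)
                elif rng.random() < absent_hit_prob:
                    ident = rng.uniform(*identity_when_absent)
                else:
                    continue
                aln_rows.append({
                    "qseqid": f"{prot}_MIT9301", "sseqid": gid,
                    "pident": round(float(ident), 1), "length": 190,
                    "mismatch": 0, "gapopen": 0, "qstart": 1, "qend": 190,
                    "sstart": 1, "send": 190, "evalue": 1e-100,
                    "bitscore": round(float(ident) * 2, 1)})
    from .survey import BLAST_COLUMNS
    return (pd.DataFrame(meta_rows),
            pd.DataFrame(aln_rows, columns=list(BLAST_COLUMNS)))


# ------------------------------------------------------------------- dataset

def write_dataset(cfg: SimConfig, outdir) -> dict[str, str]:
    """Emit every synthetic stream as CSV/TSV plus a ground-truth JSON sidecar."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    from .growth import write_growth_csv
    curves = gen_growth_curves(cfg)
    write_growth_csv(curves, out / "growth_curves.csv")

    incs = gen_tracer_incubations(cfg)
    pd.DataFrame([{
        "condition": i.condition, "dpm": i.dpm,
        "activity_uCi_ml": i.activity_added, "sa_Ci_mol": i.sa_stock,
        "carrier_uM": i.carrier_conc, "volume_ml": i.volume,
        "cells_per_ml": i.cell_density, "duration_h": i.duration,
    } for i in incs]).to_csv(out / "tracer_incubations.csv", index=False)

    frac_rng = cfg.rng("fractionation")
    frac_rows = []
    for rep in ("r1", "r2", "r3"):
        prof = gen_fractionation_profile(cfg, replicate=rep, rng=frac_rng)
        for frac, dpm in prof.dpm.items():
            frac_rows.append({"replicate": rep, "fraction": frac, "dpm": dpm,
                              "pellet_total_dpm": prof.pellet_total_dpm})
    pd.DataFrame(frac_rows).to_csv(out / "fractionation.csv", index=False)

    gen_formate_assay(cfg).to_csv(out / "formate_assay.csv", index=False)

    meta, aln = gen_survey_table(
        n_by_ocean={"NAO": 219, "NPO": 187},
        presence_prob_by_ocean={"NAO": 14 / 219, "NPO": 1 / 187},
        seed=cfg.seed)
    meta.to_csv(out / "survey_metadata.csv", index=False)
    aln.to_csv(out / "survey_alignments.tsv", sep="\t", index=False, header=False)

    truth = asdict(cfg)
    truth["growth"] = {k: asdict(v) for k, v in cfg.growth.items()}
    truth["formate_per_cell"] = dict(cfg.formate_per_cell)
    truth["fraction_props"] = dict(cfg.fraction_props)
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return {"outdir": str(out)}
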