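"""Inferential statistics and the PhnY/PhnZ genome-survey presence screen.

The survey consumes 12-column tabular protein-alignment output (the classic
outfmt-6 dialect) against the two reference proteins of the phosphonate
oxidative pathway — PhnY (an Fe(II)/alpha-ketoglutarate dioxygenase) and
PhnZ (an Fe(II)-dependent HD-superfamily oxygenase) — plus a genome-metadata
table, and screens genomes for pathway presence by best-hit protein identity.
Biogeographic enrichment is tested with a Yates-corrected two-proportion
test; culture comparisons use one-way ANOVA with Tukey HSD.

ANOVA, Tukey and the proportion test are computed from their closed forms so
every intermediate (sums of squares, expected counts) is inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BLAST_COLUMNS",
    "SurveyRecord",
    "ProportionTestResult",
    "TukeyComparison",
    "oneway_anova",
    "tukey_hsd",
    "two_proportion_test",
    "read_alignments",
    "screen_presence",
    "count_by_ocean",
    "ocean_enrichment",
]

#: Standard 12-column tabular alignment dialect.
BLAST_COLUMNS = ("qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                 "qstart", "qend", "sstart", "send", "evalue", "bitscore")

REFERENCE_PROTEINS = ("PhnY", "PhnZ")


@dataclass(frozen=True)
class SurveyRecord:
    """One genome's best identities to the two reference proteins plus metadata."""

    genome_id: str
    clade: str | None
    depth_m: float
    latitude: float
    longitude: float
    ocean: str
    identity_phnY: float | None
    identity_phnZ: float | None
    present: bool
    is_reference: bool = False


@dataclass(frozen=True)
class ProportionTestResult:
    x1: int
    n1: int
    x2: int
    n2: int
    chi2: float
    df: int
    p: float
    alternative: str
    continuity: bool


@dataclass(frozen=True)
class TukeyComparison:
    group1: str
    group2: str
    diff: float          # mean(group1) - mean(group2)
    q: float             # studentized-range statistic
    p: float
    significant: bool    # at alpha = 0.05


# ------------------------------------------------------------ ANOVA / Tukey

def oneway_anova(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA from between/within sums of squares.

    Returns (F, p).  Requires >= 2 groups with >= 2 values each.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("every group needs at least two values")
    all_vals = np.concatenate(list(arrays.values()))
    grand = all_vals.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = all_vals.size - len(arrays)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0:
        # identical values within every group: F is 0 if means agree, inf otherwise
        f = 0.0 if ss_between == 0 else float("inf")
        return f, 1.0 if ss_between == 0 else 0.0
    f = ms_between / ms_within
    return float(f), float(stats.f.sf(f, df_between, df_within))


def tukey_hsd(groups: Mapping[str, Sequence[float]],
              alpha: float = 0.05) -> list[TukeyComparison]:
    """Tukey honest-significant-difference pairwise comparisons.

    Uses the pooled ANOVA error term; for groups i, j the statistic is
    q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)) referred to the
    studentized range distribution with k groups and N-k error df
    (the Tukey-Kramer form for unequal n).
    """
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2 or any(a.size < 2 for a in arrays.values()):
        raise ValueError("Tukey HSD requires >= 2 groups with >= 2 values each")
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    df_err = n_total - k
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays.values()) / df_err

    out: list[TukeyComparison] = []
    names = sorted(arrays)
    for a_i in range(k):
        for a_j in range(a_i + 1, k):
            g1, g2 = names[a_i], names[a_j]
            m1, m2 = arrays[g1].mean(), arrays[g2].mean()
            n1, n2 = arrays[g1].size, arrays[g2].size
            se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
            if se == 0:
                q = 0.0 if m1 == m2 else float("inf")
                p = 1.0 if m1 == m2 else 0.0
            else:
                q = float(abs(m1 - m2) / se)
                p = float(stats.studentized_range.sf(q, k, df_err))
            out.append(TukeyComparison(group1=g1, group2=g2, diff=float(m1 - m2),
                                       q=q, p=p, significant=p <= alpha))
    return out


# ------------------------------------------------------- two-proportion test

def two_proportion_test(
    x1: int, n1: int, x2: int, n2: int,
    alternative: str = "two-sided",
    continuity: bool = True,
) -> ProportionTestResult:
    """Chi-square test of two proportions, optionally Yates-corrected.

    Equivalent to the squared two-proportion z-test.  With continuity
    correction the cell deviations |O - E| are shrunk by 0.5 (never past
    zero).  One-sided p is half the chi-square tail when the observed
    direction matches `alternative`, 1 minus half the tail otherwise.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie within 0..n")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError("alternative must be two-sided | greater | less")

    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    if np.any(expected == 0):
        chi2 = 0.0  # degenerate margin: no evidence either way
    else:
        dev = np.abs(obs - expected)
        if continuity:
            dev = np.maximum(dev - 0.5, 0.0)
        chi2 = float((dev ** 2 / expected).sum())

    tail = float(stats.chi2.sf(chi2, df=1))
    p1, p2 = x1 / n1, x2 / n2
    if alternative == "two-sided":
        p = tail
    else:
        matches = (p1 > p2) if alternative == "greater" else (p1 < p2)
        if p1 == p2:
            p = 0.5 if chi2 == 0 else 1.0 - tail / 2.0
        else:
            p = tail / 2.0 if matches else 1.0 - tail / 2.0
    return ProportionTestResult(x1=x1, n1=n1, x2=x2, n2=n2, chi2=chi2, df=1,
                                p=p, alternative=alternative,
                                continuity=continuity)


# ------------------------------------------------------------ presence screen

def read_alignments(path) -> pd.DataFrame:
    """Read 12-column tabular alignments (TSV, no header)."""
    df = pd.read_csv(path, sep="\t", names=list(BLAST_COLUMNS), comment="#")
    return df


def _protein_family(qseqid: str) -> str | None:
    for prot in REFERENCE_PROTEINS:
        if prot.lower() in str(qseqid).lower():
            return prot
    return None


def best_hits(alignments: pd.DataFrame) -> pd.DataFrame:
    """Best alignment per (genome, reference protein): max bitscore, tie -> max identity."""
    df = alignments.copy()
    df["protein"] = df["qseqid"].map(_protein_family)
    df = df.dropna(subset=["protein"])
    df = df.sort_values(["sseqid", "protein", "bitscore", "pident"],
                        ascending=[True, True, False, False], kind="mergesort")
    return df.groupby(["sseqid", "protein"], as_index=False).first()


def screen_presence(
    alignments: pd.DataFrame,
    metadata: pd.DataFrame,
    id_threshold: float = 97.0,
    require_both: bool = True,
    reference_ids: Iterable[str] = (),
) -> list[SurveyRecord]:
    """Flag pathway presence per genome from best-hit protein identities.

    A genome is `present` when its best-hit identity to each reference
    protein is strictly greater than `id_threshold` (to both proteins when
    `require_both`, to either otherwise).  Genomes listed in `reference_ids`
    (the query strains themselves) are flagged is_reference and never
    counted as survey detections.  Metadata columns: genome_id, clade,
    depth_m, latitude, longitude, ocean.
    """
    refs = set(reference_ids)
    hits = best_hits(alignments)
    ident: dict[tuple[str, str], float] = {
        (row.sseqid, row.protein): float(row.pident)
        for row in hits.itertuples(index=False)
    }
    records = []
    for row in metadata.itertuples(index=False):
        gid = str(row.genome_id)
        id_y = ident.get((gid, "PhnY"))
        id_z = ident.get((gid, "PhnZ"))
        above = [(i is not None and i > id_threshold) for i in (id_y, id_z)]
        present = all(above) if require_both else any(above)
        clade = getattr(row, "clade", None)
        if clade is not None and (pd.isna(clade) or clade == ""):
            clade = None
        records.append(SurveyRecord(
            genome_id=gid, clade=clade,
            depth_m=float(getattr(row, "depth_m", np.nan)),
            latitude=float(getattr(row, "latitude", np.nan)),
            longitude=float(getattr(row, "longitude", np.nan)),
            ocean=str(row.ocean),
            identity_phnY=id_y, identity_phnZ=id_z,
            present=bool(present), is_reference=gid in refs,
        ))
    return records


def count_by_ocean(records: Iterable[SurveyRecord],
                   include_references: bool = False) -> dict[str, int]:
    """Presence counts grouped by ocean; reference strains excluded by default."""
    counts: dict[str, int] = {}
    for r in records:
        if r.present and (include_references or not r.is_reference):
            counts[r.ocean] = counts.get(r.ocean, 0) + 1
    return counts


def ocean_enrichment(
    records: Iterable[SurveyRecord],
    totals_by_ocean: Mapping[str, int],
    oceans: tuple[str, str] = ("NAO", "NPO"),
    alternative: str = "greater",
    include_references: bool = True,
) -> tuple[dict[str, float], ProportionTestResult]:
    """Presence proportion per ocean plus the two-proportion enrichment test.

    The numerators include the reference strains by default: the survey
    totals count every genome from each region, the references among them.
    """
    counts = count_by_ocean(records, include_references=include_references)
    props = {oc: counts.get(oc, 0) / totals_by_ocean[oc] for oc in totals_by_ocean}
    o1, o2 = oceans
    test = two_proportion_test(counts.get(o1, 0), totals_by_ocean[o1],
                               counts.get(o2, 0), totals_by_ocean[o2],
                               alternative=alternative, continuity=True)
    return props, test


def records_to_frame(records: Iterable[SurveyRecord]) -> pd.DataFrame:
    """Tabulate survey records (mirrors the metadata columns plus results)."""
    return pd.DataFrame([{
        "genome_id": r.genome_id, "clade": r.clade, "depth_m": r.depth_m,
        "latitude": r.latitude, "longitude": r.longitude, "ocean": r.ocean,
        "identity_phnY": r.identity_phnY, "identity_phnZ": r.identity_phnZ,
        "present": r.present, "is_reference": r.is_reference,
    } for r in records])
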