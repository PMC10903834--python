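"""Range change, IUCN A3 threat categories, and vulnerability summaries.

A species' projected range change is ``(future - present) / present`` in
occupied cells.  Projected losses map onto IUCN Red List criterion A3
categories using the standard thresholds — a projected reduction of at
least 30% is Vulnerable, 50% Endangered, 80% Critically Endangered, and
total loss Extinct; anything milder (including expansion) is Least Concern.
"Threatened" means VU, EN or CR; EX is tracked separately.

Relative vulnerability is the proportion of species in a threat category,
computed per pixel (against present-day modeled richness), per family, and
per ecoregion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, random_table

from .synthetic import EcoregionMap

CATEGORIES = ("LC", "VU", "EN", "CR", "EX")
THREATENED = ("VU", "EN", "CR")
#: severity rank used for "within one category step" comparisons
SEVERITY = {c: i for i, c in enumerate(CATEGORIES)}

#: IUCN criterion A3 projected-loss thresholds (fractions)
A3_THRESHOLDS = {"VU": 0.30, "EN": 0.50, "CR": 0.80, "EX": 1.00}

SCENARIO_MATRIX = (
    "moderate_unlimited", "moderate_limited", "severe_unlimited", "severe_limited",
)


def round_half_up(x) -> np.ndarray | int:
    """Round halves away from zero toward +inf (matches reported percentages)."""
    return np.floor(np.asarray(x) + 0.5).astype(int)


# ---------------------------------------------------------------------------
# per-species assessment

@dataclass
class ThreatAssessment:
    """Range change and IUCN category for one species under one scenario."""

    species_id: str
    scenario: str
    present_cells: int
    future_cells: int
    cells_gained: int
    cells_lost: int
    change_fraction: float
    category: str


def range_change(present_binary: np.ndarray, future_binary: np.ndarray
                 ) -> tuple[int, int, float]:
    """(cells gained, cells lost, change fraction) between two binary maps."""
    present = np.asarray(present_binary).astype(bool)
    future = np.asarray(future_binary).astype(bool)
    if present.shape != future.shape:
        raise ValueError("present and future maps differ in shape")
    n_present = int(present.sum())
    if n_present == 0:
        raise ValueError("empty present range: species must be excluded")
    gained = int((future & ~present).sum())
    lost = int((present & ~future).sum())
    change = (int(future.sum()) - n_present) / n_present
    return gained, lost, change


def classify_iucn(change_fraction: float, thresholds: dict[str, float] | None = None) -> str:
    """IUCN A3 category from a range-change fraction (loss thresholds
    inclusive: a change of exactly -0.30 is VU, -1.0 is EX)."""
    if change_fraction < -1.0:
        raise ValueError(f"change fraction below -1: {change_fraction}")
    thr = A3_THRESHOLDS if thresholds is None else thresholds
    loss = -change_fraction
    if loss >= thr["EX"]:
        return "EX"
    if loss >= thr["CR"]:
        return "CR"
    if loss >= thr["EN"]:
        return "EN"
    if loss >= thr["VU"]:
        return "VU"
    return "LC"


def assess_species(
    species_id: str,
    scenario: str,
    present_binary: np.ndarray,
    future_binary: np.ndarray,
    thresholds: dict[str, float] | None = None,
) -> ThreatAssessment:
    gained, lost, change = range_change(present_binary, future_binary)
    return ThreatAssessment(
        species_id=species_id, scenario=scenario,
        present_cells=int(np.asarray(present_binary).astype(bool).sum()),
        future_cells=int(np.asarray(future_binary).astype(bool).sum()),
        cells_gained=gained, cells_lost=lost, change_fraction=change,
        category=classify_iucn(change, thresholds),
    )


def assessments_table(assessments: list[ThreatAssessment]) -> pd.DataFrame:
    """Per-species long table (species, scenario, pixels gained/lost,
    proportion change, status)."""
    return pd.DataFrame([vars(a) for a in assessments])


def category_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot an assessment table to scenario x category counts."""
    counts = (table.pivot_table(index="scenario", columns="category",
                                aggfunc="size", fill_value=0)
              .reindex(columns=list(CATEGORIES), fill_value=0))
    counts.columns.name = None
    return counts


# ---------------------------------------------------------------------------
# scenario comparison

def scenario_chisq(
    counts: pd.DataFrame,
    n_replicates: int = 2000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """Pearson chi-squared on a scenario x category table with a
    Monte-Carlo p-value.

    The null distribution is simulated by drawing *n_replicates* tables
    with both margins fixed (Patefield algorithm);
    ``p = (1 + #{simulated >= observed}) / (n_replicates + 1)``.
    Zero rows/columns are dropped with a warning.
    """
    tab = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    keep_rows = tab.sum(axis=1) > 0
    keep_cols = tab.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping all-zero rows/columns from contingency table", stacklevel=2)
        tab = tab[keep_rows][:, keep_cols]
    stat = float(chi2_contingency(tab, correction=False).statistic)
    rng = np.random.default_rng(seed)
    rows = tab.sum(axis=1).astype(int)
    cols = tab.sum(axis=0).astype(int)
    sims = random_table(rows, cols).rvs(n_replicates, random_state=rng)
    expected = np.outer(rows, cols) / rows.sum()
    sim_stats = ((sims - expected) ** 2 / expected).sum(axis=(1, 2))
    p = (1.0 + np.count_nonzero(sim_stats >= stat)) / (n_replicates + 1.0)
    return stat, float(p)


# ---------------------------------------------------------------------------
# spatial and taxonomic vulnerability

@dataclass
class VulnerabilityMap:
    """Per-pixel richness, threatened count and relative vulnerability."""

    richness: np.ndarray
    threatened: np.ndarray
    relative_vulnerability: np.ndarray  # NaN where richness is 0


def pixel_vulnerability(
    present_ranges: dict[str, np.ndarray],
    categories: dict[str, str],
) -> VulnerabilityMap:
    """Relative vulnerability per pixel.

    *present_ranges* maps species -> present-day binary map (the richness
    denominator); *categories* maps species -> IUCN category.  Only VU, EN
    and CR count as threatened; EX species contribute to richness but are
    tallied separately by callers.
    """
    if not present_ranges:
        raise ValueError("no species supplied")
    first = next(iter(present_ranges.values()))
    richness = np.zeros(first.shape, dtype=int)
    threatened = np.zeros(first.shape, dtype=int)
    for sp, pr in present_ranges.items():
        pr = np.asarray(pr).astype(bool)
        richness += pr
        if categories[sp] in THREATENED:
            threatened += pr
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(richness > 0, threatened / np.maximum(richness, 1), np.nan)
    return VulnerabilityMap(richness=richness, threatened=threatened, relative_vulnerability=rel)


def family_vulnerability(
    assessment: pd.DataFrame,
    family_lookup: pd.Series | dict[str, str],
    min_species: int = 30,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Percent threatened species per family.

    Returns (all families, families with more than *min_species* species),
    each with columns n_species, n_threatened, percent_threatened.
    """
    fam = pd.Series(family_lookup)
    df = assessment.copy()
    df["family"] = df["species_id"].map(fam)
    df["is_threatened"] = df["category"].isin(THREATENED)
    g = df.groupby("family").agg(
        n_species=("species_id", "nunique"),
        n_threatened=("is_threatened", "sum"),
    )
    g["percent_threatened"] = 100.0 * g["n_threatened"] / g["n_species"]
    g = g.sort_values("percent_threatened", ascending=False)
    return g, g[g["n_species"] > min_species]


def ecoregion_summary(
    vuln: VulnerabilityMap,
    ecoregions: EcoregionMap,
    min_pixels: int = 30,
) -> pd.DataFrame:
    """Mean relative vulnerability per ecoregion over occupied pixels.

    Regions with fewer than *min_pixels* occupied pixels are discarded; the
    table is sorted by mean proportion, descending (sd is the sample
    standard deviation).
    """
    occupied = vuln.richness > 0
    rows = []
    for rid, name in enumerate(ecoregions.names):
        in_region = occupied & (ecoregions.region_id == rid)
        n = int(in_region.sum())
        if n < min_pixels:
            continue
        vals = vuln.relative_vulnerability[in_region]
        rows.append({
            "region": name,
            "mean_proportion": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if n > 1 else 0.0,
            "richness": float(vuln.richness[in_region].mean()),
            "n_pixels": n,
            "montane": bool(ecoregions.montane[rid]),
        })
    out = pd.DataFrame(rows, columns=["region", "mean_proportion", "sd",
                                      "richness", "n_pixels", "montane"])
    return out.sort_values("mean_proportion", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# headline report

def percentage(count: int, total: int) -> int:
    """Integer percentage, rounded half-up."""
    if total <= 0:
        raise ValueError("total must be positive")
    return int(round_half_up(100.0 * count / total))


def category_report(counts: pd.DataFrame) -> dict:
    """Headline per-scenario summary from a scenario x category count table.

    Emits per-scenario category counts and rounded percentages, threatened
    (VU+EN+CR) counts and percentages, the severe/moderate threatened-count
    ratio per dispersal assumption, and the CR percentage ratio between the
    most pessimistic and most optimistic scenario.
    """
    counts = counts.reindex(columns=list(CATEGORIES), fill_value=0)
    totals = counts.sum(axis=1)
    pct = counts.apply(lambda col: round_half_up(100.0 * col / totals))
    threat = counts[list(THREATENED)].sum(axis=1)
    report = {
        "counts": counts,
        "totals": totals,
        "percentages": pct,
        "threatened_counts": threat,
        "threatened_pct": pd.Series(round_half_up(100.0 * threat / totals), index=counts.index),
        "en_cr_counts": counts[["EN", "CR"]].sum(axis=1),
        "en_cr_pct": pd.Series(round_half_up(100.0 * counts[["EN", "CR"]].sum(axis=1) / totals),
                               index=counts.index),
    }
    for disp in ("unlimited", "limited"):
        mod, sev = f"moderate_{disp}", f"severe_{disp}"
        if mod in counts.index and sev in counts.index and threat[mod] > 0:
            report[f"threatened_ratio_{disp}"] = float(threat[sev] / threat[mod])
    best, worst = "moderate_unlimited", "severe_limited"
    if best in counts.index and worst in counts.index and counts.loc[best, "CR"] > 0:
        report["cr_ratio_percent"] = int(round_half_up(
            100.0 * counts.loc[worst, "CR"] / counts.loc[best, "CR"]))
    return report
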