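"""Presence-only occurrence cleaning with step-by-step provenance.

The cleaning protocol: discard records not identified to species
(morphospecies), collapse duplicate records within a grid cell to one, and
drop species with fewer unique presences than the modelling minimum
(default 25).  Every step appends a row (families, genera, species, records)
to a provenance log so the final dataset can be audited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

REQUIRED_COLUMNS = ("species", "longitude", "latitude")

#: minimum unique presences per species used for distribution modelling
MIN_OCCURRENCES = 25


@dataclass
class PrepLog:
    """Ordered record of cleaning steps and the table size after each."""

    rows: list[dict] = field(default_factory=list)

    def append(self, step: str, table: pd.DataFrame) -> None:
        self.rows.append({
            "step": step,
            "n_families": table["family"].nunique() if "family" in table else np.nan,
            "n_genera": table["genus"].nunique() if "genus" in table else np.nan,
            "n_species": table["species"].nunique(),
            "n_records": len(table),
        })

    def to_frame(self) -> pd.DataFrame:
        if not self.rows:
            raise ValueError("no prep steps logged")
        return pd.DataFrame(self.rows)

    def validate_monotone(self) -> None:
        counts = [r["n_records"] for r in self.rows]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ValueError(f"record counts increased across prep steps: {counts}")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns {missing}")


def drop_morphospecies(table: pd.DataFrame, log: PrepLog | None = None) -> pd.DataFrame:
    """Remove records not identified to species level."""
    _check_table(table)
    if table.empty:
        raise ValueError("occurrence table is empty")
    if "is_morphospecies" in table.columns:
        out = table.loc[~table["is_morphospecies"].astype(bool)].reset_index(drop=True)
    else:
        out = table.reset_index(drop=True)
    if out.empty:
        warnings.warn("all records were morphospecies; table is now empty", stacklevel=2)
    if log is not None:
        log.append("records identified to species", out)
    return out


def deduplicate_by_pixel(table: pd.DataFrame, grid_spec: GridSpec,
                         log: PrepLog | None = None) -> pd.DataFrame:
    """Keep one record per (species, grid cell).

    The first record in input order is retained; which duplicate survives is
    immaterial for presence/absence modelling but fixing it keeps the step
    deterministic.  Records outside the grid extent raise.
    """
    _check_table(table)
    row, col = grid_spec.cell_index(table["longitude"].to_numpy(), table["latitude"].to_numpy())
    keys = pd.DataFrame({"species": table["species"].to_numpy(), "_row": row, "_col": col})
    keep = ~keys.duplicated(keep="first")
    out = table.loc[keep.to_numpy()].reset_index(drop=True)
    if log is not None:
        log.append("deduplicated by pixel", out)
    return out


def filter_min_occurrences(
    table: pd.DataFrame,
    min_n: int = MIN_OCCURRENCES,
    log: PrepLog | None = None,
    step_name: str = "removed species below minimum occurrences",
) -> tuple[pd.DataFrame, list[str]]:
    """Drop species with fewer than *min_n* records (boundary kept).

    Returns the filtered table and the list of dropped species.
    """
    _check_table(table)
    if table.empty:
        if log is not None:
            log.append(step_name, table)
        return table.reset_index(drop=True), []
    counts = table.groupby("species", sort=False)["species"].transform("size")
    keep = counts >= min_n
    dropped = sorted(table.loc[~keep, "species"].unique())
    out = table.loc[keep].reset_index(drop=True)
    if log is not None:
        log.append(step_name, out)
    return out, dropped


def prepare_occurrences(
    table: pd.DataFrame,
    grid_spec: GridSpec,
    min_n: int = MIN_OCCURRENCES,
) -> tuple[pd.DataFrame, PrepLog, list[str]]:
    """Run the full cleaning protocol in order and return (table, log, dropped).

    Order: original -> species-level records -> pixel dedup -> minimum-
    occurrence filter.  Record counts are non-increasing across the log.
    """
    log = PrepLog()
    log.append("original dataset", table)
    out = drop_morphospecies(table, log)
    if not out.empty:
        out = deduplicate_by_pixel(out, grid_spec, log)
    out, dropped = filter_min_occurrences(out, min_n=min_n, log=log)
    log.validate_monotone()
    return out, log, dropped


def summarize_prep(log: PrepLog) -> pd.DataFrame:
    """Provenance table: one row per cleaning step with taxon/record counts."""
    return log.to_frame()
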