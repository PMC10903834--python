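"""Collinearity screening of climate variables.

Pairwise Pearson correlations are computed on random points drawn from the
land mask (default 10,000); from every pair with |r| at or above the
threshold (default 0.7) the lower-priority variable is dropped, where the
priority order encodes how frequently each variable is used in plant
distribution modelling.  Absolute correlation is used: a strong negative
correlation is just as collinear as a strong positive one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import ClimateGrid

#: default priority, most- to least-preferred
DEFAULT_PRIORITY = ("tmean", "precip", "tdiurnal", "tseason", "pseason")

CORRELATION_THRESHOLD = 0.7


@dataclass
class CorrelationReport:
    """Outcome of the collinearity screen."""

    pairs: pd.DataFrame            # columns var_a, var_b, r
    retained: list[str]
    dropped: pd.DataFrame          # columns variable, against, r

    def to_frame(self) -> pd.DataFrame:
        out = self.pairs.copy()
        out["var_a_retained"] = out["var_a"].isin(self.retained)
        out["var_b_retained"] = out["var_b"].isin(self.retained)
        return out


def sample_random_points(
    climate: ClimateGrid,
    n: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Uniform random points over the land mask with variable values.

    Sampling is without replacement; if *n* exceeds the number of land
    cells, sampling falls back to with-replacement with a warning.
    """
    rows, cols = np.nonzero(climate.mask)
    if rows.size == 0:
        raise ValueError("land mask is empty")
    rng = np.random.default_rng(seed)
    replace = n > rows.size
    if replace:
        warnings.warn(
            f"requested {n} points but only {rows.size} land cells; sampling with replacement",
            stacklevel=2,
        )
    idx = rng.choice(rows.size, size=n, replace=replace)
    r, c = rows[idx], cols[idx]
    lon, lat = climate.spec.cell_center(r, c)
    out = pd.DataFrame({"row": r, "col": c, "longitude": lon, "latitude": lat})
    for v in climate.variables:
        out[v] = climate.values[v][r, c]
    return out


def select_variables(
    points: pd.DataFrame,
    threshold: float = CORRELATION_THRESHOLD,
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
    variables: list[str] | None = None,
) -> CorrelationReport:
    """Greedy collinearity elimination.

    Pairs are visited in decreasing |r|; whenever both members of a pair
    with |r| >= threshold are still retained, the lower-priority one is
    dropped (recording the retained partner that triggered the drop).  The
    retained set ends with all pairwise |r| < threshold.
    """
    if variables is None:
        variables = [c for c in points.columns if c not in ("row", "col", "longitude", "latitude")]
    missing = [v for v in variables if v not in priority]
    if missing:
        raise ValueError(f"priority order missing variables {missing}")
    rank = {v: i for i, v in enumerate(priority)}

    corr = points[variables].corr(method="pearson")
    pair_rows = []
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            pair_rows.append({"var_a": a, "var_b": b, "r": float(corr.loc[a, b])})
    pairs = pd.DataFrame(pair_rows)

    retained = set(variables)
    dropped_rows = []
    order = pairs.reindex(pairs["r"].abs().sort_values(ascending=False).index)
    for _, p in order.iterrows():
        if abs(p["r"]) < threshold:
            break
        a, b = p["var_a"], p["var_b"]
        if a in retained and b in retained:
            loser = a if rank[a] > rank[b] else b
            winner = b if loser == a else a
            retained.discard(loser)
            dropped_rows.append({"variable": loser, "against": winner, "r": float(p["r"])})
    retained_list = [v for v in variables if v in retained]
    return CorrelationReport(
        pairs=pairs,
        retained=retained_list,
        dropped=pd.DataFrame(dropped_rows, columns=["variable", "against", "r"]),
    )
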