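"""Virtual landscapes and virtual species with known truth.

Everything downstream of this module (occurrence prep, ensemble SDMs,
dispersal correction, IUCN classification, driver regression) can be
exercised against *known* truth: each virtual species has an explicit
climatic response, explicit present/future suitability surfaces, and an
explicit true range change per future scenario.

The landscape is an abstract lon/lat rectangle with an elevation surface;
temperature variables decrease with elevation (standard lapse behaviour),
precipitation increases, and future scenarios shift the variables with a
configurable mean shift plus an elevation-dependent pattern (e.g. stronger
warming in the lowlands).  Species respond to climate through a product of
independent Gaussian responses — the standard virtual-species construction —
so suitability is 1 at the niche optimum and the "true range" is the set of
cells with suitability at or above a fixed truth threshold (default 0.5).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from sklearn.cluster import KMeans

from .grids import CLIMATE_VARIABLES, NONNEGATIVE_VARIABLES, SCENARIOS, ClimateGrid, GridSpec

FUTURE_SCENARIOS = ("future_moderate", "future_severe")

# Present-day generating parameters: (base level, elevation coefficient per
# km, noise SD).  Chosen to resemble tropical lowland-to-montane gradients:
# ~6.5 degC/km lapse rate, wetter and more diurnally variable uplands.
_PRESENT_FIELDS = {
    "tmean": (27.0, -6.5, 0.6),
    "tdiurnal": (9.0, 1.2, 0.8),
    "tseason": (1.2, 0.35, 0.25),
    "precip": (1800.0, 650.0, 350.0),
    "pseason": (55.0, -6.0, 9.0),
}


def default_scenario_deltas() -> dict[str, dict[str, dict[str, float]]]:
    """Per-variable mean shift and lowland-amplification gradient for the two
    future scenarios (severe = 2x moderate, mirroring a moderate vs severe
    emissions pathway)."""
    moderate = {
        "tmean": {"shift": 1.8, "elevation_gradient": 0.4, "pattern_sd": 0.25},
        "tdiurnal": {"shift": 0.35, "elevation_gradient": 0.0, "pattern_sd": 0.12},
        "tseason": {"shift": 0.15, "elevation_gradient": 0.0, "pattern_sd": 0.06},
        "precip": {"shift": -160.0, "elevation_gradient": 0.0, "pattern_sd": 60.0},
        "pseason": {"shift": 5.0, "elevation_gradient": 0.0, "pattern_sd": 2.0},
    }
    severe = {
        var: {k: 2.0 * v for k, v in d.items()} for var, d in moderate.items()
    }
    return {"future_moderate": moderate, "future_severe": severe}


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], scale: float = 6.0) -> np.ndarray:
    """Smooth standardized Gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=scale, mode="reflect")
    return (f - f.mean()) / f.std()


def generate_climate(
    grid_shape: tuple[int, int] = (100, 100),
    seed: int | np.random.SeedSequence = 0,
    scenario_deltas: dict | None = None,
    *,
    resolution: float = 0.05,
    xmin: float = -95.0,
    ymin: float = 5.0,
    km_per_cell: float = 5.0,
    sea_fraction: float = 0.08,
    max_elevation_km: float = 3.0,
    collinearity: tuple[str, str, float] | None = None,
) -> dict[str, ClimateGrid]:
    """Generate present plus two future climate grids.

    Parameters
    ----------
    grid_shape
        (nrows, ncols), at least 20 x 20.
    scenario_deltas
        Mapping ``scenario -> variable -> {"shift", "elevation_gradient"}``
        for every climate variable (floats are accepted as shift-only).
        Defaults to :func:`default_scenario_deltas`.
    collinearity
        Optional ``(var_a, var_b, r)``: variable *b* is reconstructed as a
        blend of *a* and an orthogonal residual so that the Pearson
        correlation over land cells equals *r* (used to exercise the
        collinearity filter).
    """
    nrows, ncols = grid_shape
    if nrows < 20 or ncols < 20:
        raise ValueError(f"grid_shape must be at least 20x20, got {grid_shape}")
    if resolution <= 0:
        raise ValueError(f"resolution must be positive, got {resolution}")
    deltas = default_scenario_deltas() if scenario_deltas is None else scenario_deltas
    for scen in FUTURE_SCENARIOS:
        if scen not in deltas:
            raise ValueError(f"scenario_deltas missing scenario {scen!r}")
        missing = [v for v in CLIMATE_VARIABLES if v not in deltas[scen]]
        if missing:
            raise ValueError(f"delta spec for {scen!r} missing variables {missing}")

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    spec = GridSpec(xmin=xmin, ymin=ymin, nrows=nrows, ncols=ncols, resolution=resolution)

    # Elevation: smooth field; lowest cells become sea (outside the mask).
    relief = _smooth_field(rng, grid_shape, scale=max(6.0, min(grid_shape) / 12))
    sea_level = np.quantile(relief, sea_fraction)
    mask = relief >= sea_level
    elev_km = np.where(mask, (relief - sea_level) / (relief.max() - sea_level) * max_elevation_km, np.nan)

    values: dict[str, np.ndarray] = {}
    for var, (base, elev_coef, noise_sd) in _PRESENT_FIELDS.items():
        noise = _smooth_field(rng, grid_shape, scale=3.0)
        arr = base + elev_coef * np.where(mask, elev_km, 0.0) + noise_sd * noise
        values[var] = arr

    if collinearity is not None:
        var_a, var_b, r_target = collinearity
        if not -1.0 <= r_target <= 1.0:
            raise ValueError("requested correlation must be in [-1, 1]")
        a = values[var_a][mask]
        b = values[var_b][mask]
        za = (a - a.mean()) / a.std()
        zb = (b - b.mean()) / b.std()
        resid = zb - (zb @ za / za.size) * za  # orthogonalize
        resid /= resid.std()
        blended = r_target * za + np.sqrt(max(0.0, 1.0 - r_target**2)) * resid
        new_b = b.mean() + b.std() * blended
        out = values[var_b].copy()
        out[mask] = new_b
        values[var_b] = out

    for var in NONNEGATIVE_VARIABLES:
        values[var] = np.clip(values[var], 0.0, None)

    grids: dict[str, ClimateGrid] = {}
    grids["present"] = ClimateGrid(
        spec=spec, values=values, mask=mask, scenario_label="present",
        elevation=elev_km, km_per_cell=km_per_cell,
    )
    elev0 = np.where(mask, elev_km, 0.0)
    mean_elev = elev_km[mask].mean()
    # one pattern field per variable, shared between scenarios, so that
    # doubling (shift, gradient, pattern_sd) doubles the delta cellwise
    pattern = {var: _smooth_field(rng, grid_shape, scale=4.0) for var in CLIMATE_VARIABLES}
    for scen in FUTURE_SCENARIOS:
        fut_values: dict[str, np.ndarray] = {}
        for var in CLIMATE_VARIABLES:
            d = deltas[scen][var]
            if isinstance(d, (int, float)):
                shift, grad, psd = float(d), 0.0, 0.0
            else:
                shift = float(d["shift"])
                grad = float(d.get("elevation_gradient", 0.0))
                psd = float(d.get("pattern_sd", 0.0))
            # positive gradient amplifies the shift below mean elevation
            delta_field = (shift
                           + grad * (mean_elev - elev0) * np.sign(shift if shift != 0 else 1.0)
                           + psd * pattern[var])
            fut = values[var] + delta_field
            if var in NONNEGATIVE_VARIABLES:
                fut = np.clip(fut, 0.0, None)
            fut_values[var] = fut
        grids[scen] = ClimateGrid(
            spec=spec, values=fut_values, mask=mask, scenario_label=scen,
            elevation=elev_km, km_per_cell=km_per_cell,
        )
    for g in grids.values():
        g.validate()
    return grids


@dataclass
class NicheSpec:
    """Controls where virtual-species optima sit and how narrow niches are.

    Breadths are multiples of each variable's SD over the land mask; montane
    specialists are seeded in the top elevation quartile with narrower
    niches, which is what makes them vulnerable to upslope range contraction.
    """

    montane_fraction: float = 0.5
    montane_elev_quantile: float = 0.75
    lowland_elev_quantile: float = 0.50
    breadth_montane: float = 0.85
    breadth_lowland: float = 1.3
    truth_threshold: float = 0.5
    n_families: int = 12


@dataclass
class VirtualSpeciesTruth:
    """A simulated taxon with a known climatic response and known ranges."""

    species_id: str
    family: str
    genus: str
    is_montane: bool
    optima: dict[str, float]
    breadths: dict[str, float]
    suitability: dict[str, np.ndarray]
    true_range: dict[str, np.ndarray]
    true_range_change: dict[str, float]
    seed_cell: tuple[int, int]

    @property
    def present_cells(self) -> int:
        return int(self.true_range["present"].sum())


def _gaussian_suitability(grid: ClimateGrid, optima: dict[str, float],
                          breadths: dict[str, float]) -> np.ndarray:
    z2 = np.zeros(grid.spec.shape)
    for var, mu in optima.items():
        sigma = breadths[var]
        z2 = z2 + ((grid.values[var] - mu) / sigma) ** 2
    suit = np.exp(-0.5 * z2)
    return np.where(grid.mask, suit, 0.0)


def generate_virtual_species(
    n_species: int,
    climate: dict[str, ClimateGrid],
    niche_spec: NicheSpec | None = None,
    seed: int | np.random.SeedSequence = 0,
    *,
    min_present_cells: int = 1,
    max_retries: int = 50,
) -> list[VirtualSpeciesTruth]:
    """Draw *n_species* virtual species and compute their truth maps.

    Each species' optimum is the present-day climate at a randomly chosen
    seed cell (montane or lowland depending on the niche spec), so present
    suitability is exactly 1 there.  Species whose present true range has
    fewer than *min_present_cells* cells are redrawn.
    """
    if n_species < 1:
        raise ValueError(f"n_species must be >= 1, got {n_species}")
    spec = niche_spec or NicheSpec()
    present = climate["present"]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    elev = present.elevation
    land_rows, land_cols = np.nonzero(present.mask)
    land_elev = elev[land_rows, land_cols]
    hi_cut = np.quantile(land_elev, spec.montane_elev_quantile)
    lo_cut = np.quantile(land_elev, spec.lowland_elev_quantile)
    montane_pool = np.nonzero(land_elev >= hi_cut)[0]
    lowland_pool = np.nonzero(land_elev <= lo_cut)[0]
    var_sd = {v: float(present.values[v][present.mask].std()) for v in present.variables}

    species: list[VirtualSpeciesTruth] = []
    n_montane = int(round(spec.montane_fraction * n_species))
    for i in range(n_species):
        is_montane = i < n_montane
        pool = montane_pool if is_montane else lowland_pool
        breadth_factor = spec.breadth_montane if is_montane else spec.breadth_lowland
        for attempt in range(max_retries):
            k = int(rng.choice(pool))
            r0, c0 = int(land_rows[k]), int(land_cols[k])
            optima = {v: float(present.values[v][r0, c0]) for v in present.variables}
            breadths = {v: breadth_factor * var_sd[v] for v in present.variables}
            suit = {s: _gaussian_suitability(g, optima, breadths) for s, g in climate.items()}
            ranges = {s: m >= spec.truth_threshold for s, m in suit.items()}
            n_present = int(ranges["present"].sum())
            if n_present >= min_present_cells:
                break
        else:
            raise RuntimeError(f"could not place species {i} with a non-empty present range")
        change = {
            s: (int(ranges[s].sum()) - n_present) / n_present for s in ranges if s != "present"
        }
        species.append(VirtualSpeciesTruth(
            species_id=f"Sp{i + 1:04d}", family="", genus="", is_montane=is_montane,
            optima=optima, breadths=breadths, suitability=suit,
            true_range=ranges, true_range_change=change, seed_cell=(r0, c0),
        ))

    _assign_families(species, n_families=min(spec.n_families, n_species),
                     seed=np.random.default_rng(ss.spawn(1)[0]))
    return species


def _assign_families(species: list[VirtualSpeciesTruth], n_families: int,
                     seed: np.random.Generator) -> None:
    """Cluster niche optima into families (and sub-split into genera) so that
    family-level vulnerability contrasts exist."""
    X = np.array([[sp.optima[v] for v in CLIMATE_VARIABLES] for sp in species])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    km = KMeans(n_clusters=n_families, n_init=4,
                random_state=int(seed.integers(2**31)))
    labels = km.fit_predict(X)
    for i, sp in enumerate(species):
        fam = int(labels[i])
        sp.family = f"Family{fam + 1:02d}"
        sp.genus = f"Genus{fam + 1:02d}{chr(ord('a') + (i % 3))}"


def sample_occurrences(
    truths: list[VirtualSpeciesTruth],
    climate_present: ClimateGrid,
    n_per_species: int = 200,
    bias_strength: float = 0.0,
    seed: int | np.random.SeedSequence = 0,
    *,
    morphospecies_fraction: float = 0.0,
) -> pd.DataFrame:
    """Draw presence-only records from each species' present true range.

    Cells are drawn with probability proportional to suitability times a
    smooth sampling-effort surface (``effort = exp(bias * field)``); draws
    are with replacement, so duplicate cell records occur and exercise
    deduplication.  Coordinates are cell centers.  A fraction of records can
    be degraded to morphospecies (identified to genus only).
    """
    if n_per_species < 1:
        raise ValueError(f"n_per_species must be >= 1, got {n_per_species}")
    if bias_strength < 0:
        raise ValueError("bias_strength must be >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    spec = climate_present.spec
    if bias_strength > 0:
        effort = np.exp(bias_strength * _smooth_field(rng, spec.shape, scale=4.0))
    else:
        effort = np.ones(spec.shape)

    frames = []
    for sp in truths:
        in_range = sp.true_range["present"]
        rows, cols = np.nonzero(in_range)
        if rows.size == 0:
            raise ValueError(f"species {sp.species_id!r} has an empty present range")
        w = sp.suitability["present"][rows, cols] * effort[rows, cols]
        p = w / w.sum()
        draw = rng.choice(rows.size, size=n_per_species, replace=True, p=p)
        lon, lat = spec.cell_center(rows[draw], cols[draw])
        n = n_per_species
        morpho = rng.random(n) < morphospecies_fraction
        ids = np.where(morpho, sp.genus + "_sp", sp.species_id)
        frames.append(pd.DataFrame({
            "species": ids,
            "genus": sp.genus,
            "family": sp.family,
            "longitude": lon,
            "latitude": lat,
            "source": "synthetic",
            "is_morphospecies": morpho,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class EcoregionMap:
    """Contiguous partition of the land mask into named regions."""

    region_id: np.ndarray          # int array, -1 outside mask
    names: list[str]
    montane: np.ndarray            # bool per region
    mean_elevation: np.ndarray     # km per region

    @property
    def n_regions(self) -> int:
        return len(self.names)


def generate_ecoregions(
    climate: ClimateGrid,
    n_regions: int = 10,
    seed: int | np.random.SeedSequence = 0,
    *,
    montane_quantile: float = 0.75,
) -> EcoregionMap:
    """Partition the land mask into contiguous regions by multi-source
    breadth-first growth from random seed cells; flag regions whose mean
    elevation exceeds the landscape's *montane_quantile* elevation."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    mask = climate.mask
    n_land = int(mask.sum())
    if n_regions > n_land:
        raise ValueError(f"n_regions={n_regions} exceeds number of land cells ({n_land})")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    rows, cols = np.nonzero(mask)
    seeds = rng.choice(rows.size, size=n_regions, replace=False)

    region = np.full(mask.shape, -1, dtype=int)
    queue: deque[tuple[int, int]] = deque()
    for rid, k in enumerate(seeds):
        region[rows[k], cols[k]] = rid
        queue.append((int(rows[k]), int(cols[k])))
    nrows, ncols = mask.shape
    while queue:
        r, c = queue.popleft()
        rid = region[r, c]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrows and 0 <= cc < ncols and mask[rr, cc] and region[rr, cc] < 0:
                region[rr, cc] = rid
                queue.append((rr, cc))
    # disconnected land pockets unreached by BFS: attach to nearest assigned cell
    unassigned = np.nonzero(mask & (region < 0))
    if unassigned[0].size:
        assigned = np.nonzero(region >= 0)
        for r, c in zip(*unassigned):
            d2 = (assigned[0] - r) ** 2 + (assigned[1] - c) ** 2
            j = int(np.argmin(d2))
            region[r, c] = region[assigned[0][j], assigned[1][j]]

    elev = climate.elevation
    cut = np.quantile(elev[mask], montane_quantile) if montane_quantile > 0 else -np.inf
    mean_elev = np.array([elev[region == rid].mean() for rid in range(n_regions)])
    montane = mean_elev > cut if np.isfinite(cut) else np.ones(n_regions, dtype=bool)
    names = [f"Region{rid + 1:02d}" for rid in range(n_regions)]
    return EcoregionMap(region_id=region, names=names, montane=montane, mean_elevation=mean_elev)
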