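"""End-to-end orchestration: synthetic data -> occurrence prep -> variable
selection -> ensemble SDMs -> dispersal-limited projection -> IUCN A3
classification -> vulnerability maps -> driver importance -> report.

The experimental design is the 2 x 2 scenario matrix {moderate, severe
emissions} x {limited, unlimited dispersal}.  A single master seed drives
every stage through spawned child seeds, so a run is fully reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import climate_select, dispersal, drivers, ensemble, occurrences, report, synthetic, vulnerability
from .grids import ClimateGrid, write_ascii_grid, write_climate_grid

RCP_TO_SCENARIO = {"moderate": "future_moderate", "severe": "future_severe"}


@dataclass
class RunConfig:
    """All pipeline parameters; validated before any stage runs."""

    seed: int = 0
    # landscape
    grid_shape: tuple[int, int] = (60, 60)
    resolution: float = 0.05
    km_per_cell: float = 5.0
    collinearity: tuple[str, str, float] | None = ("tseason", "tmean", 0.85)
    scenario_deltas: dict | None = None
    # species & sampling
    n_species: int = 20
    montane_fraction: float = 0.5
    breadth_montane: float = 0.85
    breadth_lowland: float = 1.3
    truth_threshold: float = 0.5
    n_families: int = 12
    n_occurrences: int = 200
    bias_strength: float = 0.0
    morphospecies_fraction: float = 0.02
    # prep & variable selection
    min_occurrences: int = 25
    n_random_points: int = 2000
    corr_threshold: float = 0.7
    priority: tuple[str, ...] = climate_select.DEFAULT_PRIORITY
    # SDM ensemble
    n_background: int = 1000
    techniques: tuple[str, ...] = ensemble.TECHNIQUES
    n_replicates: int = 10
    train_frac: float = 0.7
    tss_min: float = 0.7
    # dispersal & classification
    decay_scale_km: float = 100.0
    a3_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(vulnerability.A3_THRESHOLDS))
    # summaries
    n_regions: int = 10
    montane_quantile: float = 0.75
    min_region_pixels: int = 30
    family_min_species: int = 30
    chisq_replicates: int = 2000
    # drivers
    driver_scenario: str = "severe_limited"
    driver_n_iter: int = 200
    driver_n_points: int = 500
    run_drivers: bool = True

    def validate(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if not 0 < self.train_frac < 1:
            raise ValueError("train_frac must be in (0, 1)")
        if self.decay_scale_km <= 0:
            raise ValueError("decay_scale_km must be positive")
        if self.driver_scenario not in vulnerability.SCENARIO_MATRIX:
            raise ValueError(f"driver_scenario must be one of {vulnerability.SCENARIO_MATRIX}")

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "priority", "techniques", "collinearity"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    config: RunConfig
    climate: dict[str, ClimateGrid]
    truths: list[synthetic.VirtualSpeciesTruth]
    ecoregions: synthetic.EcoregionMap
    occurrences_raw: pd.DataFrame
    occurrences: pd.DataFrame
    prep_log: pd.DataFrame
    dropped_species: list[str]
    correlation: climate_select.CorrelationReport
    selected_variables: list[str]
    evaluation: pd.DataFrame
    not_modeled: list[str]
    assessments: pd.DataFrame
    counts: pd.DataFrame
    chisq: tuple[float, float]
    report: dict
    vulnerability_maps: dict[str, vulnerability.VulnerabilityMap]
    family_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]]
    ecoregion_tables: dict[str, pd.DataFrame]
    driver_results: drivers.DriverImportanceResults | None

    @property
    def modeled_species(self) -> list[str]:
        return sorted(self.assessments["species_id"].unique())


def _stage(name):
    """Wrap stage errors with the stage name so failures are attributable."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            return False
    return _Ctx()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig, outdir: str | None = None) -> PipelineResult:
    """Run every stage; optionally persist all artifacts under *outdir*."""
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    (s_clim, s_species, s_occ, s_regions, s_points, s_bg, s_fit, s_chisq, s_drv) = ss.spawn(9)

    with _stage("synthetic climate"):
        climate = synthetic.generate_climate(
            grid_shape=config.grid_shape, seed=s_clim,
            scenario_deltas=config.scenario_deltas,
            resolution=config.resolution, km_per_cell=config.km_per_cell,
            collinearity=config.collinearity,
        )
        spec = climate["present"].spec

    with _stage("virtual species"):
        niche = synthetic.NicheSpec(
            montane_fraction=config.montane_fraction,
            breadth_montane=config.breadth_montane,
            breadth_lowland=config.breadth_lowland,
            truth_threshold=config.truth_threshold,
            n_families=config.n_families,
        )
        truths = synthetic.generate_virtual_species(
            config.n_species, climate, niche, seed=s_species)
        truth_by_id = {t.species_id: t for t in truths}
        ecoregions = synthetic.generate_ecoregions(
            climate["present"], n_regions=config.n_regions, seed=s_regions,
            montane_quantile=config.montane_quantile)

    with _stage("occurrence sampling"):
        occ_raw = synthetic.sample_occurrences(
            truths, climate["present"], n_per_species=config.n_occurrences,
            bias_strength=config.bias_strength, seed=s_occ,
            morphospecies_fraction=config.morphospecies_fraction)

    with _stage("occurrence prep"):
        occ, log, dropped = occurrences.prepare_occurrences(
            occ_raw, spec, min_n=config.min_occurrences)
        prep_log = log.to_frame()

    with _stage("variable selection"):
        points = climate_select.sample_random_points(
            climate["present"], n=config.n_random_points, seed=s_points)
        corr = climate_select.select_variables(
            points, threshold=config.corr_threshold, priority=config.priority)
        selected = corr.retained
        model_climate = {s: g.subset(selected) for s, g in climate.items()}

    with _stage("sdm ensemble"):
        bg = ensemble.make_background(climate["present"], n=config.n_background, seed=s_bg)
        species_ids = sorted(occ["species"].unique())
        fit_seeds = s_fit.spawn(len(species_ids))
        eval_frames, not_modeled, assessments = [], [], []
        present_ranges: dict[str, np.ndarray] = {}
        cats: dict[str, dict[str, str]] = {sc: {} for sc in vulnerability.SCENARIO_MATRIX}
        for sp_id, sp_seed in zip(species_ids, fit_seeds):
            sub = occ[occ["species"] == sp_id]
            rows, cols = spec.cell_index(sub["longitude"].to_numpy(), sub["latitude"].to_numpy())
            sdm = ensemble.EnsembleSDM(
                (rows, cols), model_climate, bg, species_id=sp_id,
                techniques=config.techniques, n_replicates=config.n_replicates,
                train_frac=config.train_frac, tss_min=config.tss_min,
            )
            res = sdm.fit(seed=sp_seed)
            eval_frames.append(res.evaluation_table())
            if res.not_modeled:
                not_modeled.append(sp_id)
                continue
            present_bin = res.binary_range("present")
            if present_bin.sum() == 0:
                not_modeled.append(sp_id)
                continue
            present_ranges[sp_id] = sdm.land_vector_to_map(
                present_bin.astype(float), fill=0.0) > 0.5
            dist = dispersal.distance_to_presence(rows, cols, spec.shape,
                                                  km_per_cell=config.km_per_cell)
            dist_land = dist[sdm._land]
            for rcp, scen in RCP_TO_SCENARIO.items():
                suit = res.suitability[scen]
                damped = dispersal.apply_decay(suit, dist_land, config.decay_scale_km)
                for disp_label, s in (("unlimited", suit), ("limited", damped)):
                    future_bin = ensemble.binarize(s, res.threshold)
                    scen_label = f"{rcp}_{disp_label}"
                    a = vulnerability.assess_species(
                        sp_id, scen_label, present_bin, future_bin,
                        thresholds=config.a3_thresholds)
                    assessments.append(a)
                    cats[scen_label][sp_id] = a.category
        evaluation = pd.concat(eval_frames, ignore_index=True) if eval_frames else pd.DataFrame()
        if not assessments:
            raise PipelineError("stage 'sdm ensemble' failed: no species could be modeled")
        assess_df = vulnerability.assessments_table(assessments)

    with _stage("vulnerability"):
        counts = vulnerability.category_counts(assess_df)
        chisq = vulnerability.scenario_chisq(counts, n_replicates=config.chisq_replicates,
                                             seed=s_chisq)
        rep = vulnerability.category_report(counts)
        family_lookup = {t.species_id: t.family for t in truths}
        vuln_maps, fam_tables, eco_tables = {}, {}, {}
        for scen_label in vulnerability.SCENARIO_MATRIX:
            vm = vulnerability.pixel_vulnerability(present_ranges, cats[scen_label])
            vuln_maps[scen_label] = vm
            fam_tables[scen_label] = vulnerability.family_vulnerability(
                assess_df[assess_df["scenario"] == scen_label], family_lookup,
                min_species=config.family_min_species)
            eco_tables[scen_label] = vulnerability.ecoregion_summary(
                vm, ecoregions, min_pixels=config.min_region_pixels)

    driver_res = None
    if config.run_drivers:
        with _stage("drivers"):
            rcp = config.driver_scenario.split("_")[0]
            ds = drivers.build_driver_dataset(
                vuln_maps[config.driver_scenario],
                model_climate["present"], model_climate[RCP_TO_SCENARIO[rcp]],
                ecoregions=ecoregions)
            n_points = min(config.driver_n_points, len(ds))
            driver_res = drivers.DriverImportanceModel(ds).fit(
                n_iter=config.driver_n_iter, n_points=n_points, seed=s_drv)

    result = PipelineResult(
        config=config, climate=climate, truths=truths, ecoregions=ecoregions,
        occurrences_raw=occ_raw, occurrences=occ, prep_log=prep_log,
        dropped_species=dropped, correlation=corr, selected_variables=selected,
        evaluation=evaluation, not_modeled=not_modeled, assessments=assess_df,
        counts=counts, chisq=chisq, report=rep, vulnerability_maps=vuln_maps,
        family_tables=fam_tables, ecoregion_tables=eco_tables,
        driver_results=driver_res,
    )
    if outdir is not None:
        write_artifacts(result, outdir)
    return result


def write_artifacts(result: PipelineResult, outdir: str) -> None:
    """Persist every table, raster and plot of a run."""
    os.makedirs(outdir, exist_ok=True)
    cfg = result.config
    cfg.to_yaml(os.path.join(outdir, "config.yaml"))
    result.occurrences_raw.to_csv(os.path.join(outdir, "occurrences_raw.csv"), index=False)
    result.occurrences.to_csv(os.path.join(outdir, "occurrences_clean.csv"), index=False)
    result.prep_log.to_csv(os.path.join(outdir, "prep_log.csv"), index=False)
    result.correlation.to_frame().to_csv(os.path.join(outdir, "correlation_report.csv"), index=False)
    result.evaluation.to_csv(os.path.join(outdir, "model_evaluation.csv"), index=False)
    result.assessments.to_csv(os.path.join(outdir, "species_assessments.csv"), index=False)
    result.counts.to_csv(os.path.join(outdir, "category_counts.csv"))
    result.report["percentages"].to_csv(os.path.join(outdir, "category_percentages.csv"))
    for scen, (fam_all, fam_big) in result.family_tables.items():
        fam_all.to_csv(os.path.join(outdir, f"family_vulnerability_{scen}.csv"))
    for scen, tab in result.ecoregion_tables.items():
        tab.to_csv(os.path.join(outdir, f"ecoregion_summary_{scen}.csv"), index=False)
    if result.driver_results is not None:
        result.driver_results.importance.to_csv(
            os.path.join(outdir, "driver_importance.csv"), index=False)
        result.driver_results.coefficients.to_csv(
            os.path.join(outdir, "driver_coefficients.csv"), index=False)

    rasters = os.path.join(outdir, "rasters")
    os.makedirs(rasters, exist_ok=True)
    for grid in result.climate.values():
        write_climate_grid(grid, rasters)
    spec = result.climate["present"].spec
    mask = result.climate["present"].mask
    for scen, vm in result.vulnerability_maps.items():
        write_ascii_grid(os.path.join(rasters, f"relative_vulnerability_{scen}.asc"),
                         vm.relative_vulnerability, spec, mask)

    figdir = os.path.join(outdir, "figures")
    os.makedirs(figdir, exist_ok=True)
    report.plot_category_breakdown(result.counts, os.path.join(figdir, "category_breakdown.png"))
    for scen, vm in result.vulnerability_maps.items():
        report.plot_vulnerability_map(vm, os.path.join(figdir, f"vulnerability_{scen}.png"),
                                      title=scen)
    fam_all, _ = result.family_tables[cfg.driver_scenario]
    report.plot_family_bars(fam_all, os.path.join(figdir, "family_vulnerability.png"))

    chisq_stat, chisq_p = result.chisq
    summary = {
        "n_species_simulated": cfg.n_species,
        "n_species_modeled": len(result.modeled_species),
        "n_species_not_modeled": len(result.not_modeled),
        "n_species_dropped_in_prep": len(result.dropped_species),
        "selected_variables": result.selected_variables,
        "threatened_pct": {k: int(v) for k, v in result.report["threatened_pct"].items()},
        "chisq_statistic": chisq_stat,
        "chisq_p_value": chisq_p,
    }
    if result.driver_results is not None:
        summary["top_driver"] = str(result.driver_results.table.iloc[0]["variable"])
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
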