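"""End-to-end orchestration: config → kriged fields → isotherms → report.

The pipeline reproduces the full analysis chain on either real input files
(tow CSV + gridded SST) or the synthetic generator: 5-yearly monthly
kriging of log(n+1) abundance and SST, isotherm latitude tracking at 11, 12
and 13 °C, percent-north range trajectories, Chelton-adjusted plasticity
tests, movement/abundance summaries (one report row per taxon) and the
seasonal-peak phenology comparison over the warming period.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gridding, synthetic
from .grids import GridSpec, PeriodGrid, PeriodIndex, frame_to_grids, grids_to_frame, standard_periods
from .isotherms import IsothermTrack, isotherm_tracks, mean_isotherm_latitude
from .ranges import (
    RangeTrajectory,
    displacement_km,
    per_decade_velocity,
    population_index,
    range_trajectory,
)
from .reference import COOLING_PAIR, WARMING_PAIR, summarize_groups
from .stats import (
    PlasticityResult,
    SeasonalProfile,
    TaxonClassification,
    abundance_sst_correlation,
    classify_taxon,
    phenological_shift,
    phenology_vs_range,
    plasticity_test,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``tows_path``/``sst_path`` point at input files, or a synthetic
    block (scenario + sampling + taxa) generates them.  All randomness is
    seeded from ``seed``.
    """

    taxa: list[synthetic.TaxonSpec] = field(default_factory=list)
    scenario: synthetic.SSTScenario | None = None
    sampling: synthetic.SamplingPlan | None = None
    tows_path: str | None = None
    sst_path: str | None = None
    grid: GridSpec = field(default_factory=GridSpec)
    isotherm_temps: tuple[float, ...] = (11.0, 12.0, 13.0)
    diel_taxa: tuple[str, ...] = ()
    groups: dict[str, str] = field(default_factory=dict)  # taxon -> group label
    alpha: float = 0.05
    log_base: float | None = None
    min_samples: int = gridding.MIN_SAMPLES_PER_BUCKET
    sst_grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        temps = tuple(float(t) for t in self.isotherm_temps)
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("isotherm temperatures must be strictly increasing")
        self.isotherm_temps = temps

    @property
    def periods(self) -> list[PeriodIndex]:
        return standard_periods()

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        cfg = dict(cfg)
        if "scenario" in cfg and isinstance(cfg["scenario"], dict):
            sc = dict(cfg["scenario"])
            if "trend_segments" in sc:
                sc["trend_segments"] = tuple(tuple(seg) for seg in sc["trend_segments"])
            cfg["scenario"] = synthetic.SSTScenario(**sc)
        if "sampling" in cfg and isinstance(cfg["sampling"], dict):
            cfg["sampling"] = synthetic.SamplingPlan(**cfg["sampling"])
        if "taxa" in cfg:
            cfg["taxa"] = [
                t if isinstance(t, synthetic.TaxonSpec) else synthetic.TaxonSpec(**t)
                for t in cfg["taxa"]
            ]
        if "isotherm_temps" in cfg:
            cfg["isotherm_temps"] = tuple(cfg["isotherm_temps"])
        if "diel_taxa" in cfg:
            cfg["diel_taxa"] = tuple(cfg["diel_taxa"])
        return cls(**cfg)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def demo_config(n_tows_per_year: int = 2000, seed: int = 76542) -> RunConfig:
    """Bundled demonstration: one niche-conservative and one niche-plastic taxon
    under the default cooling-then-warming scenario, with fixed seeds."""
    scenario = synthetic.SSTScenario(seed=seed)
    plan = synthetic.SamplingPlan(n_tows_per_year=n_tows_per_year, seed=seed + 1)
    taxa = [
        synthetic.TaxonSpec(
            name="conservative_tracker",
            niche_mode="conservative",
            thermal_optimum=12.0,
            thermal_sd=1.0,
            seed=seed + 11,
        ),
        synthetic.TaxonSpec(
            name="plastic_resident",
            niche_mode="plastic",
            home_latitude=54.5,
            home_sd=2.5,
            seed=seed + 12,
        ),
    ]
    return RunConfig(taxa=taxa, scenario=scenario, sampling=plan, seed=seed)


@dataclass
class PipelineResult:
    config: RunConfig
    periods: list[PeriodIndex]
    sst_fields: dict[PeriodIndex, PeriodGrid]
    tracks: dict[float, dict[PeriodIndex, IsothermTrack]]
    isotherm_mean_lat: dict[float, np.ndarray]
    sst_series: np.ndarray
    taxon_fields: dict[str, dict[PeriodIndex, PeriodGrid]]
    trajectories: dict[str, RangeTrajectory]
    plasticity: dict[str, dict[float, PlasticityResult]]
    classifications: dict[str, TaxonClassification]
    monthly_population: pd.DataFrame  # taxon, period, month, population_index
    phenology: pd.DataFrame
    report: pd.DataFrame
    summary: dict


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.tows_path and config.sst_path:
        return gridding.read_tows(config.tows_path), gridding.read_sst(config.sst_path)
    if config.scenario is None or config.sampling is None or not config.taxa:
        raise ValueError("no taxa: provide input paths or a synthetic block with taxa")
    log.info("simulating inputs (seed %d)", config.seed)
    sst = synthetic.generate_sst_field(
        config.scenario, grid_step=config.sst_grid_step, domain=config.grid
    )
    tows = synthetic.generate_tows(config.sampling, config.scenario, config.taxa)
    return tows, sst


def _taxon_names(config: RunConfig, tows: pd.DataFrame) -> list[str]:
    if config.taxa:
        return [t.name for t in config.taxa]
    return sorted(tows["taxon"].unique())


def _monthly_population(
    monthly: dict[tuple[PeriodIndex, int], PeriodGrid], taxon: str
) -> pd.DataFrame:
    rows = [
        {
            "taxon": taxon,
            "period": p.label,
            "month": m,
            "population_index": population_index(g),
        }
        for (p, m), g in sorted(monthly.items())
    ]
    return pd.DataFrame(rows, columns=["taxon", "period", "month", "population_index"])


def _seasonal_profile(monthly_pop: pd.DataFrame, taxon: str, period: PeriodIndex) -> SeasonalProfile:
    sub = monthly_pop[(monthly_pop["taxon"] == taxon) & (monthly_pop["period"] == period.label)]
    x = np.zeros(12)
    for _, row in sub.iterrows():
        x[int(row["month"]) - 1] = max(float(row["population_index"]), 0.0)
    return SeasonalProfile(taxon=taxon, window=period.label, x_m=x)


def analyze(
    config: RunConfig,
    sst_fields: dict[PeriodIndex, PeriodGrid],
    taxon_fields: dict[str, dict[PeriodIndex, PeriodGrid]],
    monthly_population: pd.DataFrame,
) -> PipelineResult:
    """Statistical stage: everything downstream of the kriged fields.

    Shared by the full run and the from-cached-grids path, so re-analysis of
    serialized intermediate grids reproduces the report exactly.
    """
    periods = sorted(sst_fields)
    tracks = isotherm_tracks(sst_fields, config.isotherm_temps)
    iso_mean = {
        temp: np.array([mean_isotherm_latitude(tr[p]) for p in periods])
        for temp, tr in tracks.items()
    }
    sst_series = np.array([population_index(sst_fields[p]) for p in periods])

    cooling, warming = COOLING_PAIR, WARMING_PAIR
    warm_idx = [i for i, p in enumerate(periods) if warming[0] <= p <= warming[1]]
    warming_window = slice(warm_idx[0], warm_idx[-1] + 1) if len(warm_idx) >= 5 else None

    trajectories: dict[str, RangeTrajectory] = {}
    plasticity: dict[str, dict[float, PlasticityResult]] = {}
    classifications: dict[str, TaxonClassification] = {}
    pheno_rows = []
    report_rows = []
    for taxon in sorted(taxon_fields):
        fields = taxon_fields[taxon]
        tperiods = sorted(fields)
        traj = range_trajectory(taxon, fields, {
            temp: {p: tracks[temp][p] for p in tperiods} for temp in tracks
        })
        trajectories[taxon] = traj
        pidx = [periods.index(p) for p in tperiods]
        results = {
            temp: plasticity_test(
                traj.percent_north_z[temp],
                iso_mean[temp][pidx],
                alpha=config.alpha,
                taxon=taxon,
                isotherm_temp=temp,
            )
            for temp in sorted(tracks)
        }
        plasticity[taxon] = results
        sst_sign = abundance_sst_correlation(
            traj.population_index,
            sst_series[pidx],
            warming_window=warming_window if tperiods == periods else None,
            alpha=config.alpha,
        )
        cls = classify_taxon(
            results,
            tperiods,
            traj.median_latitude,
            traj.population_index,
            cooling,
            warming,
            sst_sign=sst_sign,
        )
        classifications[taxon] = cls

        p_start = _seasonal_profile(monthly_population, taxon, warming[0])
        p_end = _seasonal_profile(monthly_population, taxon, warming[1])
        shift = phenological_shift(p_start, p_end)
        pheno_rows.append(
            {
                "taxon": taxon,
                "seasonal_peak_start": p_start.seasonal_peak,
                "seasonal_peak_end": p_end.seasonal_peak,
                "phenological_shift_months": shift,
                "movement_warming_km": cls.movement_warming_km,
            }
        )

        row = {
            "taxon": taxon,
            "group": config.groups.get(taxon, ""),
            "verdict": cls.verdict,
            "n_isotherms_negative": cls.n_significant,
            "movement_cooling_km": cls.movement_cooling_km,
            "movement_warming_km": cls.movement_warming_km,
            "warming_km_per_decade": per_decade_velocity(cls.movement_warming_km, *warming),
            "sst_correlation_sign": cls.sst_correlation_sign,
            "abundance_mean": cls.abundance_mean,
            "abundance_sd": cls.abundance_sd,
        }
        for temp in sorted(results):
            r = results[temp]
            row[f"r_{temp:g}C"] = r.r
            row[f"p_{temp:g}C"] = r.p_one_sided
            row[f"neff_{temp:g}C"] = r.n_eff
        report_rows.append(row)

    report = pd.DataFrame(report_rows)
    phenology = pd.DataFrame(pheno_rows)
    summary = summarize_groups(report) if not report.empty else {}
    summary["isotherms"] = {
        f"{temp:g}C": {
            "cooling_km": displacement_km(
                mean_isotherm_latitude(tracks[temp][cooling[0]]),
                mean_isotherm_latitude(tracks[temp][cooling[1]]),
            ),
            "warming_km": displacement_km(
                mean_isotherm_latitude(tracks[temp][warming[0]]),
                mean_isotherm_latitude(tracks[temp][warming[1]]),
            ),
        }
        for temp in sorted(tracks)
    }
    for temp, vals in summary["isotherms"].items():
        vals["warming_km_per_decade"] = per_decade_velocity(vals["warming_km"], *warming)

    # cross-taxon phenology-vs-movement correlation per group (>= 4 taxa)
    summary["phenology_vs_range"] = {}
    if config.groups and not phenology.empty:
        pheno = phenology.assign(group=[config.groups.get(t, "") for t in phenology["taxon"]])
        for grp, sub in pheno.groupby("group"):
            if len(sub) < 4 or not grp:
                continue
            try:
                r, p = phenology_vs_range(
                    sub["phenological_shift_months"], sub["movement_warming_km"]
                )
                summary["phenology_vs_range"][grp] = {"r": r, "p": p, "n": len(sub)}
            except ValueError as err:
                summary["phenology_vs_range"][grp] = {"degenerate": str(err)}

    return PipelineResult(
        config=config,
        periods=periods,
        sst_fields=sst_fields,
        tracks=tracks,
        isotherm_mean_lat=iso_mean,
        sst_series=sst_series,
        taxon_fields=taxon_fields,
        trajectories=trajectories,
        plasticity=plasticity,
        classifications=classifications,
        monthly_population=monthly_population,
        phenology=phenology,
        report=report,
        summary=summary,
    )


def run_pipeline(config: RunConfig, outdir: str | Path | None = None) -> PipelineResult:
    """Full run: inputs → gridding → analysis; optionally write all outputs."""
    tows, sst = _load_inputs(config)
    sst_fields = gridding.grid_sst(sst, config.grid, config.periods)
    taxon_fields: dict[str, dict[PeriodIndex, PeriodGrid]] = {}
    monthly_frames = []
    for taxon in _taxon_names(config, tows):
        fields, monthly = gridding.grid_taxon(
            tows,
            taxon,
            config.grid,
            config.periods,
            diel_set=set(config.diel_taxa),
            min_samples=config.min_samples,
            log_base=config.log_base,
            keep_monthly=True,
        )
        if not fields:
            log.warning("taxon %s produced no kriged periods; dropped from report", taxon)
            continue
        taxon_fields[taxon] = fields
        monthly_frames.append(_monthly_population(monthly, taxon))
    monthly_population = (
        pd.concat(monthly_frames, ignore_index=True)
        if monthly_frames
        else pd.DataFrame(columns=["taxon", "period", "month", "population_index"])
    )
    result = analyze(config, sst_fields, taxon_fields, monthly_population)
    if outdir is not None:
        write_outputs(result, outdir)
    return result


def write_outputs(result: PipelineResult, outdir: str | Path) -> None:
    """Serialize report, trajectories, isotherms, phenology and cached grids."""
    out = Path(outdir)
    (out / "grids").mkdir(parents=True, exist_ok=True)
    result.report.to_csv(out / "report.csv", index=False)
    result.phenology.to_csv(out / "phenology.csv", index=False)
    if result.trajectories:
        pd.concat(
            [t.to_frame() for _, t in sorted(result.trajectories.items())], ignore_index=True
        ).to_csv(out / "trajectories.csv", index=False)
    track_frames = [
        result.tracks[temp][p].to_frame() for temp in sorted(result.tracks)
        for p in sorted(result.tracks[temp])
    ]
    pd.concat(track_frames, ignore_index=True).to_csv(out / "isotherm_tracks.csv", index=False)
    pd.DataFrame(
        [
            {
                "temp": temp,
                "period": p.label,
                "mean_latitude": result.isotherm_mean_lat[temp][i],
            }
            for temp in sorted(result.isotherm_mean_lat)
            for i, p in enumerate(result.periods)
        ]
    ).to_csv(out / "isotherm_summary.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    grids_to_frame(result.sst_fields).to_csv(out / "grids" / "sst.csv", index=False)
    for taxon, fields in sorted(result.taxon_fields.items()):
        grids_to_frame(fields).to_csv(out / "grids" / f"{taxon}.csv", index=False)
    result.monthly_population.to_csv(out / "monthly_population.csv", index=False)


def analyze_from_cache(config: RunConfig, outdir: str | Path) -> PipelineResult:
    """Recompute the statistical stage from serialized intermediate grids."""
    out = Path(outdir)
    sst_fields = frame_to_grids(pd.read_csv(out / "grids" / "sst.csv"), config.grid, kind="sst")
    taxon_fields = {}
    for path in sorted((out / "grids").glob("*.csv")):
        if path.stem == "sst":
            continue
        taxon_fields[path.stem] = frame_to_grids(pd.read_csv(path), config.grid, kind=path.stem)
    monthly_population = pd.read_csv(out / "monthly_population.csv")
    return analyze(config, sst_fields, taxon_fields, monthly_population)
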