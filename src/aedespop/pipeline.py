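"""End-to-end orchestration of the two evaluation modes.

*Full customization* (productivity-rich site): build the replicated grid,
fit the food coefficients on a calibration grid distinct from the evaluation
grid, run replicate simulations, and evaluate the spatial structure of
per-house pupal production (global autocorrelation, second-order L
increments, local hot-spot membership).

*Weather-only customization* (abundance-only site): carry a donor grid and
donor food coefficients over unchanged, swap in local weather, recalibrate
only the overall food scale F0 against an observed ovitrap-positivity
series, and report the weekly positivity overlay.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import habitat, weather as weather_mod
from .calibration import (
    CalibrationResult,
    PositivitySeries,
    ProductivityTable,
    calibrate_overall_F0,
    calibrate_type_coefficients,
    ovitrap_positivity,
)
from .habitat import SimulationGrid, build_replicated_grid
from .simulator import BiologyParams, SimOutput, run_simulation
from .spatial_stats import (
    CountMap,
    cluster_size_profile,
    l_statistics,
    morans_i,
)
from .synthetic_data import (
    SurveyGenParams,
    TargetGenParams,
    generate_positivity_series,
    generate_survey_subset,
    generate_target_productivity,
)

__all__ = ["RunConfig", "EvaluationReport", "run_full_customization",
           "run_weather_only"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    mode: str = "full-customization"  # or "weather-only"
    seed: int = 0
    # weather: either a file path or a synthetic block
    weather_path: str | None = None
    weather_regime: str = "equatorial"  # "equatorial" | "temperate"
    n_days: int = 1095
    # survey: either a file path or synthetic defaults
    survey_path: str | None = None
    survey_params: SurveyGenParams = field(default_factory=SurveyGenParams)
    n_copies: int = 4
    tiling: tuple[int, int] | None = None
    # targets
    target_path: str | None = None
    positivity_path: str | None = None
    # simulation
    burn_in_days: int = 365
    horizon: int | None = None
    replicates: int = 20
    # calibration
    calib_replicates: int = 3
    calib_tol: float = 0.02
    calib_max_iter: int = 10
    # evaluation
    distances: tuple[int, ...] = tuple(range(1, 11))
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "survey_params" in raw:
            raw["survey_params"] = SurveyGenParams(**raw["survey_params"])
        if "tiling" in raw and raw["tiling"] is not None:
            raw["tiling"] = tuple(raw["tiling"])
        if "distances" in raw:
            raw["distances"] = tuple(raw["distances"])
        return cls(**raw)


@dataclass
class EvaluationReport:
    """Machine-readable tables mirroring the evaluation figures."""

    mode: str
    seeds: dict
    calibration: CalibrationResult | None
    pupal_series: pd.DataFrame            # per-replicate daily pupal totals
    productivity: pd.DataFrame | None     # simulated vs target shares per type
    moran_table: pd.DataFrame | None      # I, E[I], Z, p per replicate
    l_profile: pd.DataFrame | None        # mean delta(d) and envelope
    cluster_profile: pd.DataFrame | None  # members per distance
    positivity: pd.DataFrame | None       # weekly overlay sim vs target

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.pupal_series.to_csv(out / "pupal_series.csv", index=False)
        for name, df in [
            ("productivity", self.productivity),
            ("moran", self.moran_table),
            ("l_profile", self.l_profile),
            ("cluster_profile", self.cluster_profile),
            ("positivity", self.positivity),
        ]:
            if df is not None:
                df.to_csv(out / f"{name}.csv", index=False)
        meta = {"mode": self.mode, "seeds": self.seeds}
        if self.calibration is not None:
            meta["calibration"] = self.calibration.to_json_dict()
        (out / "metadata.json").write_text(json.dumps(meta, indent=2))


def _load_weather(config: RunConfig, seed: int):
    if config.weather_path:
        return weather_mod.read_weather(config.weather_path)
    regime = (
        weather_mod.equatorial_regime()
        if config.weather_regime == "equatorial"
        else weather_mod.temperate_regime()
    )
    return weather_mod.generate_weather(regime, config.n_days, seed)


def _load_survey(config: RunConfig, seed: int):
    if config.survey_path:
        return habitat.read_survey(config.survey_path)
    return generate_survey_subset(config.survey_params, seed)


def _load_target(config: RunConfig, seed: int) -> ProductivityTable:
    if config.target_path:
        return ProductivityTable.from_csv(config.target_path)
    return generate_target_productivity(TargetGenParams(), seed)


def _load_positivity(config: RunConfig, seed: int) -> PositivitySeries:
    if config.positivity_path:
        return PositivitySeries.from_csv(config.positivity_path)
    regime = "temperate" if config.weather_regime == "temperate" else "equatorial"
    return generate_positivity_series(regime, max(52, config.n_days // 7), seed=seed)


def _replicate_outputs(grid, weather, params, config, seeds) -> list[SimOutput]:
    return [
        run_simulation(grid, weather, params, config.burn_in_days, int(s),
                       horizon=config.horizon)
        for s in seeds
    ]


def _spatial_tables(outputs, grid, seed, distances, n_perm=199):
    moran_rows = []
    deltas = []
    cluster_counts = {int(d): {"positive": 0, "negative": 0} for d in distances}
    d_max = max(distances)
    for k, out in enumerate(outputs):
        counts = out.pupae_produced_per_house().astype(float)
        cm = CountMap(counts, grid.positions())
        if counts.std() == 0:
            continue
        m = morans_i(cm, n_perm=n_perm, seed=seed + k)
        moran_rows.append(
            {"replicate": k, "I": m.I, "expected": m.expected, "z": m.z,
             "p": m.p_value}
        )
        lr = l_statistics(cm, d_max)
        deltas.append(lr.delta)
        prof = cluster_size_profile(cm, distances)
        for d, v in prof.items():
            cluster_counts[d]["positive"] += v["positive"]
            cluster_counts[d]["negative"] += v["negative"]
    moran_df = pd.DataFrame(moran_rows)
    if deltas:
        deltas = np.vstack(deltas)
        l_df = pd.DataFrame(
            {
                "d": np.arange(1, d_max + 1),
                "delta_mean": deltas.mean(axis=0),
                "delta_lo": deltas.min(axis=0),
                "delta_hi": deltas.max(axis=0),
            }
        )
    else:
        l_df = None
    cl_df = pd.DataFrame(
        [
            {"d": d, "positive_members": v["positive"],
             "negative_members": v["negative"]}
            for d, v in sorted(cluster_counts.items())
        ]
    )
    return moran_df, l_df, cl_df


def run_full_customization(
    config: RunConfig, params0: BiologyParams | None = None
) -> EvaluationReport:
    """Calibrate on a distinct calibration grid, evaluate on the replicated grid.

    The calibration grid is built from a survey block disjoint from the
    evaluation one (synthetic surveys use an independent seed), honoring the
    calibration-set / simulation-set split.
    """
    params0 = params0 or BiologyParams()
    rng = np.random.default_rng(config.seed)
    s_weather, s_survey, s_calib_survey, s_target, s_calib, s_sim = (
        int(x) for x in rng.integers(0, 2**31 - 1, size=6)
    )
    weather = _load_weather(config, s_weather)
    survey = _load_survey(config, s_survey)
    p = config.survey_params
    eval_grid = build_replicated_grid(
        survey, p.n_rows, p.n_cols, config.n_copies, s_sim, tiling=config.tiling
    )
    calib_survey = (
        generate_survey_subset(p, s_calib_survey)
        if config.survey_path is None
        else survey
    )
    calib_grid = build_replicated_grid(
        calib_survey, p.n_rows, p.n_cols, 1, s_calib
    )
    target = _load_target(config, s_target)
    # a target may carry mass on types neither grid holds (small synthetic
    # surveys can miss rare categories): project and renormalize
    types_of = lambda g: {c.type_name for h in g.houses for c in h.containers}
    target = target.restricted_to(types_of(calib_grid) & types_of(eval_grid))

    calib = calibrate_type_coefficients(
        calib_grid, weather, target, params0,
        replicates=config.calib_replicates, tol=config.calib_tol,
        max_iter=config.calib_max_iter, seed=s_calib,
        burn_in_days=config.burn_in_days, horizon=config.horizon,
    )
    params = calib.params(params0)

    rep_seeds = [int(x) for x in rng.integers(0, 2**31 - 1, size=config.replicates)]
    outputs = _replicate_outputs(eval_grid, weather, params, config, rep_seeds)

    pupal = pd.DataFrame(
        {f"rep{k}": out.totals["pupae"].to_numpy() for k, out in enumerate(outputs)}
    )
    pupal.insert(0, "day", np.arange(len(pupal)))

    sim_shares = np.mean([o.per_type_shares().to_numpy() for o in outputs], axis=0)
    prod = pd.DataFrame(
        {
            "type": list(habitat.CONTAINER_TYPES),
            "simulated_share": sim_shares,
            "target_share": target.as_array(),
        }
    )

    moran_df, l_df, cl_df = _spatial_tables(
        outputs, eval_grid, config.seed, config.distances
    )

    report = EvaluationReport(
        mode="full-customization",
        seeds={
            "config": config.seed, "weather": s_weather, "survey": s_survey,
            "calibration_survey": s_calib_survey, "target": s_target,
            "calibration": s_calib, "grid": s_sim, "replicates": rep_seeds,
        },
        calibration=calib,
        pupal_series=pupal,
        productivity=prod,
        moran_table=moran_df,
        l_profile=l_df,
        cluster_profile=cl_df,
        positivity=None,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run_weather_only(
    config: RunConfig,
    donor_grid: SimulationGrid,
    donor_params: BiologyParams,
    target: PositivitySeries | None = None,
) -> EvaluationReport:
    """Swap weather, recalibrate F0 only, overlay weekly positivity.

    ``donor_grid`` and ``donor_params`` come from a prior full-customization
    run; container composition and alpha/beta coefficients are carried over
    unchanged.
    """
    if donor_params is None or donor_grid is None:
        raise ValueError("weather-only mode requires donor grid and coefficients")
    rng = np.random.default_rng(config.seed)
    s_weather, s_pos, s_calib = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    weather = _load_weather(config, s_weather)
    if target is None:
        target = _load_positivity(config, s_pos)

    calib = calibrate_overall_F0(
        donor_grid, weather, target, donor_params,
        tol=config.calib_tol, max_iter=config.calib_max_iter, seed=s_calib,
        burn_in_days=config.burn_in_days, horizon=config.horizon,
    )
    params = calib.params(donor_params)

    rep_seeds = [int(x) for x in rng.integers(0, 2**31 - 1, size=config.replicates)]
    outputs = _replicate_outputs(donor_grid, weather, params, config, rep_seeds)

    weekly = np.vstack(
        [ovitrap_positivity(o).weekly().fraction for o in outputs]
    )
    n_weeks = weekly.shape[1]
    target_frac = target.fraction[:n_weeks]
    pos_df = pd.DataFrame(
        {
            "week": np.arange(n_weeks),
            "sim_mean": weekly.mean(axis=0),
            "sim_lo": np.quantile(weekly, 0.025, axis=0),
            "sim_hi": np.quantile(weekly, 0.975, axis=0),
            "target": np.pad(target_frac, (0, n_weeks - len(target_frac)),
                             constant_values=np.nan),
            "zero_weeks": (weekly == 0).all(axis=0),
        }
    )

    pupal = pd.DataFrame(
        {f"rep{k}": out.totals["pupae"].to_numpy() for k, out in enumerate(outputs)}
    )
    pupal.insert(0, "day", np.arange(len(pupal)))

    report = EvaluationReport(
        mode="weather-only",
        seeds={"config": config.seed, "weather": s_weather,
               "positivity": s_pos, "calibration": s_calib,
               "replicates": rep_seeds},
        calibration=calib,
        pupal_series=pupal,
        productivity=None,
        moran_table=None,
        l_profile=None,
        cluster_profile=None,
        positivity=pos_df,
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report
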