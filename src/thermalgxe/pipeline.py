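"""End-to-end analysis pipeline and its run configuration.

``run_pipeline`` ties the stages together: obtain data (simulate a scenario
or read weather/plot CSVs), accumulate thermal profiles, then produce
environment summaries, genotype × environment predicted means, stability
rankings, GGE biplot scores, heritability estimates, thermal-trait
correlations and exponential yield trends — each written as a headered CSV
to the output directory alongside a JSON manifest that fully determines the
run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import association, heritability, io, stability, summaries
from .simulate import (
    default_locations,
    default_panel,
    default_response,
    default_sowing_dates,
    plots_to_frame,
    simulate_trial,
)
from .thermal import ThermalConfig, profiles_table

log = logging.getLogger("thermalgxe")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialisable to the manifest."""

    out_dir: str = "thermalgxe-out"
    seed: int = 0
    # simulation scenario (used when no input CSVs are given)
    n_genotypes: int = 148
    n_desi: int = 10
    n_reps: int = 2
    heat_sensitivity_scale: float = 1.2e-3
    # pre-existing data (weather CSV per location + plots CSV)
    weather_csvs: dict[str, str] = field(default_factory=dict)
    plots_csv: str | None = None
    # thermal constants
    t_base: float = 10.0
    t_growth_ceiling: float = 30.0
    t_stress_ceiling: float = 50.0
    capping_rule: str = "cap_max_floor_min"
    traits: tuple[str, ...] = ("yield_g", "hsw_g")
    log_level: str = "INFO"

    def thermal_config(self) -> ThermalConfig:
        return ThermalConfig(
            t_base=self.t_base,
            t_growth_ceiling=self.t_growth_ceiling,
            t_stress_ceiling=self.t_stress_ceiling,
            capping_rule=self.capping_rule,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (.yml/.yaml) or TOML (.toml)."""
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            payload = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            import tomllib

            payload = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"unsupported config format: {path.suffix!r}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "traits" in payload:
            payload["traits"] = tuple(payload["traits"])
        return cls(**payload)


def _stage(name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", name, dt, exc)
            return False

    return _Timer()


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute every analysis stage; returns the written artifact paths."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    thermal_cfg = config.thermal_config()
    paths: dict[str, Path] = {}

    with _stage("data"):
        if config.plots_csv:
            plots = io.read_plots_csv(config.plots_csv)
            weather = {
                loc: io.read_weather_csv(p) for loc, p in config.weather_csvs.items()
            }
        else:
            panel = default_panel(
                n_genotypes=config.n_genotypes,
                n_desi=config.n_desi,
                seed=config.seed,
                heat_sensitivity_scale=config.heat_sensitivity_scale,
            )
            plots, weather = simulate_trial(
                panel,
                default_locations(),
                default_sowing_dates(),
                n_reps=config.n_reps,
                response=default_response(),
                config=thermal_cfg,
                seed=config.seed,
            )
            paths["plots"] = io.write_plots_csv(plots, out / "plots.csv")
            for loc, wx in weather.items():
                paths[f"weather_{loc}"] = io.write_weather_csv(
                    wx, out / f"weather_{loc}.csv"
                )

    with _stage("thermal"):
        profiles = profiles_table(plots, weather, thermal_cfg)
        paths["thermal"] = out / "thermal_profiles.csv"
        profiles.to_csv(paths["thermal"], index=False)

    with _stage("summaries"):
        tables = [
            summaries.environment_summary(plots, profiles, stage)
            for stage in ("vegetative", "reproductive", "full_season")
        ]
        paths["environment_summary"] = out / "environment_summary.csv"
        pd.concat(tables, ignore_index=True).to_csv(
            paths["environment_summary"], index=False
        )
        for trait in config.traits:
            table = summaries.predicted_means(plots, trait)
            p = out / f"gxe_means_{trait}.csv"
            table.data.to_csv(p)
            paths[f"gxe_means_{trait}"] = p

    with _stage("stability"):
        frames = []
        locations = sorted(plots_to_frame(plots)["location"].unique())
        for trait in config.traits:
            for loc in locations:
                table = summaries.predicted_means(plots, trait, by=f"tos_within:{loc}")
                res = stability.stability_table(table)
                frame = res.table.copy()
                frame.insert(0, "location", loc)
                frame.insert(0, "trait", trait)
                frames.append(frame)
        paths["stability"] = out / "stability.csv"
        pd.concat(frames, ignore_index=True).to_csv(paths["stability"], index=False)

    with _stage("gge"):
        score_frames = []
        for trait in config.traits:
            table = summaries.predicted_means(plots, trait)
            res = stability.gge_decompose(table)
            g = res.genotype_scores.copy()
            g.insert(0, "kind", "genotype")
            e = res.environment_scores.copy()
            e.insert(0, "kind", "environment")
            scores = pd.concat([g, e])
            scores.insert(0, "trait", trait)
            scores.insert(
                1, "pc1_pct", res.pc_variance_pct[0]
            )
            scores.insert(2, "pc2_pct", res.pc_variance_pct[1])
            score_frames.append(scores.rename_axis("id").reset_index())
        paths["gge"] = out / "gge_scores.csv"
        pd.concat(score_frames, ignore_index=True).to_csv(paths["gge"], index=False)

    with _stage("heritability"):
        results = heritability.heritability_by_environment(plots, config.traits)
        paths["heritability"] = out / "heritability.csv"
        pd.DataFrame(
            {
                "environment": [r.environment for r in results],
                "trait": [r.trait for r in results],
                "s_g2": [r.s_g2 for r in results],
                "s_e2": [r.s_e2 for r in results],
                "r": [r.r for r in results],
                "h2": [r.h2 for r in results],
            }
        ).to_csv(paths["heritability"], index=False)

    with _stage("correlations"):
        corr = association.correlate_thermal_traits(
            plots, profiles, periods=("vegetative", "reproductive", "full_season")
        )
        paths["correlations"] = out / "correlations.csv"
        association.correlations_frame(corr).to_csv(paths["correlations"], index=False)

        trend_rows = []
        means = association._mean_level_table(plots, profiles, "vegetative")
        for loc, grp in means.groupby("location", sort=True):
            ok = grp["yield_g"] > 0
            for thermal in ("gdd", "sdd"):
                x = grp.loc[ok, thermal]
                if x.nunique() < 3:
                    continue
                fit = association.fit_exponential_trend(x, grp.loc[ok, "yield_g"])
                trend_rows.append(
                    {
                        "location": loc, "period": "vegetative", "thermal": thermal,
                        "a": fit.a, "b": fit.b, "r2": fit.r2, "n": int(ok.sum()),
                    }
                )
        paths["trends"] = out / "yield_trends.csv"
        pd.DataFrame(trend_rows).to_csv(paths["trends"], index=False)

    with _stage("manifest"):
        from . import __version__

        manifest = {
            "config": dataclasses.asdict(config),
            "version": __version__,
            "outputs": {k: str(v) for k, v in paths.items()},
        }
        mpath = out / "manifest.json"
        mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
        paths["manifest"] = mpath

    return paths
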