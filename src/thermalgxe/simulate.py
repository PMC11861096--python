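"""Synthetic multi-environment chickpea trial generator.

Emulates the structure of a two-location, two-sowing-time heat-stress trial:
a hot, stable tropical site where the crop is otherwise unstressed
("ideal"), and a temperate, variable site typical of Mediterranean-type
chickpea production.  The delayed time of sowing (TOS 2) shifts reproduction
into hotter conditions, imposing heat stress.

Weather is a seasonal sinusoid in the daily mean with Gaussian noise and a
fixed diurnal range.  Phenology is thermal-time driven: each genotype
carries GDD requirements for flowering and maturity, so the hotter site
flowers earlier in calendar time.  Plot traits follow an explicit response
model in which yield is environmentally plastic — a multiplicative penalty
proportional to accumulated Stress Degree Days, with genotype-specific heat
sensitivity — while 100-seed weight is predominantly genotypic with only a
small additive stress term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date
from datetime import timedelta

import numpy as np
import pandas as pd

from .thermal import (
    StageWindow,
    ThermalConfig,
    _contributions,
    as_weather_frame,
    compute_sdd,
)

__all__ = [
    "GenotypeSpec",
    "LocationProfile",
    "PlotRecord",
    "ResponseModel",
    "default_locations",
    "default_panel",
    "default_response",
    "generate_weather",
    "plots_to_frame",
    "simulate_phenology",
    "simulate_trial",
]


@dataclass(frozen=True)
class LocationProfile:
    """Seasonal temperature regime of one trial site.

    The daily mean follows ``mean_temp + amplitude * sin(2*pi*(doy - phase_day)
    / period)`` plus N(0, daily_noise_sd) noise; tmax/tmin sit half a diurnal
    range either side of that mean.
    """

    name: str
    mean_temp: float
    amplitude: float
    phase_day: float
    diurnal_range: float
    daily_noise_sd: float
    period: float = 365.25

    def __post_init__(self) -> None:
        if self.diurnal_range <= 0:
            raise ValueError("diurnal_range must be positive")
        if self.daily_noise_sd < 0:
            raise ValueError("daily_noise_sd must be non-negative")


@dataclass(frozen=True)
class GenotypeSpec:
    """One genotype's thermal requirements and trait potentials.

    ``heat_sensitivity`` is the fraction of yield lost per unit of
    full-season SDD (°C·day); 0 marks a fully heat-tolerant genotype.
    """

    id: int
    type: str  # "desi" | "kabuli"
    origin: str
    flowering_requirement: float
    maturity_requirement: float
    yield_potential: float
    hsw_potential: float
    heat_sensitivity: float

    def __post_init__(self) -> None:
        if not 0 < self.flowering_requirement < self.maturity_requirement:
            raise ValueError(
                f"genotype {self.id}: need 0 < flowering_requirement "
                f"< maturity_requirement"
            )
        if self.yield_potential <= 0 or self.hsw_potential <= 0:
            raise ValueError(f"genotype {self.id}: potentials must be positive")
        if self.heat_sensitivity < 0:
            raise ValueError(f"genotype {self.id}: heat_sensitivity must be >= 0")


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: design position, phenology dates and harvest traits.

    ``maturity_date`` may be ``None`` for plots never scored as mature; such
    records keep their vegetative stage but reproductive and full-season
    statistics are unavailable.
    """

    plot_id: str
    genotype_id: int
    location: str
    tos: int
    replicate: int
    sowing_date: Date
    flowering_date: Date
    maturity_date: Date | None
    yield_g: float
    hsw_g: float
    plot_area_m2: float = 8.0

    def __post_init__(self) -> None:
        ordered = self.sowing_date <= self.flowering_date and (
            self.maturity_date is None or self.flowering_date <= self.maturity_date
        )
        if not ordered:
            raise ValueError(
                f"plot {self.plot_id}: phenology dates out of order"
            )
        if self.yield_g < 0:
            raise ValueError(f"plot {self.plot_id}: negative yield")
        if self.hsw_g <= 0:
            raise ValueError(f"plot {self.plot_id}: non-positive HSW")


@dataclass(frozen=True)
class ResponseModel:
    """Trait response surface for the simulated trial.

    Yield (grams/plot):  (mu + loc_offset + g_i + e_j + ge_ij + block + eps) *
    max(0, 1 - heat_sensitivity_i * sdd_penalty_yield * moderation_loc * SDD_j),
    floored at 0.  HSW (grams): additive genotype-dominated model with a small
    SDD penalty.  Environment effects are drawn once per environment from
    N(0, env_sd); ``site_stress_moderation`` scales the heat penalty per
    location (an irrigated site buffers heat through transpiration cooling,
    so its large SDD burden translates into much less yield loss than the
    same SDD would cost a rainfed site); ``location_*_offset`` are fixed
    site fertility/management effects.
    """

    yield_mean: float = 2000.0
    yield_genotype_sd: float = 200.0
    yield_env_sd: float = 60.0
    yield_gxe_sd: float = 110.0
    yield_block_sd: float = 40.0
    yield_residual_sd: float = 250.0
    sdd_penalty_yield: float = 1.0  # scales genotype heat_sensitivity
    hsw_mean: float = 35.0
    hsw_genotype_sd: float = 5.0
    hsw_env_sd: float = 0.5
    hsw_gxe_sd: float = 0.4
    hsw_block_sd: float = 0.15
    hsw_residual_sd: float = 1.5
    sdd_penalty_hsw: float = 0.002  # grams lost per SDD unit
    site_stress_moderation: dict = field(default_factory=lambda: {"hotsite": 0.2})
    location_yield_offset: dict = field(default_factory=lambda: {"hotsite": 600.0})
    location_hsw_offset: dict = field(default_factory=lambda: {"hotsite": 3.0})

    def __post_init__(self) -> None:
        for name in (
            "yield_genotype_sd", "yield_env_sd", "yield_gxe_sd",
            "yield_block_sd", "yield_residual_sd", "hsw_genotype_sd",
            "hsw_env_sd", "hsw_gxe_sd", "hsw_block_sd", "hsw_residual_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def generate_weather(
    profile: LocationProfile, start_date: Date, n_days: int, seed: int
) -> pd.DataFrame:
    """Daily weather series (date, tmin, tmax) for one location."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    t = np.arange(n_days, dtype=float) + float(start_date.timetuple().tm_yday)
    mean = profile.mean_temp + profile.amplitude * np.sin(
        2 * np.pi * (t - profile.phase_day) / profile.period
    )
    mean = mean + rng.normal(0.0, profile.daily_noise_sd, size=n_days)
    dates = [start_date + timedelta(days=i) for i in range(n_days)]
    return pd.DataFrame(
        {
            "date": dates,
            "tmin": mean - profile.diurnal_range / 2.0,
            "tmax": mean + profile.diurnal_range / 2.0,
        }
    )


class HorizonError(ValueError):
    """A thermal requirement is unreachable within the weather series."""


def simulate_phenology(
    genotype: GenotypeSpec,
    weather,
    sowing_date: Date,
    config: ThermalConfig | None = None,
) -> tuple[Date, Date]:
    """First dates at which cumulative GDD from sowing meets each requirement."""
    config = config or ThermalConfig()
    frame = as_weather_frame(weather)
    sub = frame.loc[frame["date"] >= sowing_date]
    if sub.empty or sub["date"].iloc[0] != sowing_date:
        raise HorizonError(f"weather series does not cover sowing date {sowing_date}")
    contrib = _contributions(
        sub["tmin"].to_numpy(float),
        sub["tmax"].to_numpy(float),
        config.t_base,
        config.t_growth_ceiling,
        config.capping_rule,
    )
    cum = np.cumsum(contrib)
    dates = list(sub["date"])

    def first_reach(req: float) -> Date:
        if req <= 0:
            return sowing_date
        idx = int(np.searchsorted(cum, req, side="left"))
        if idx >= len(cum) or cum[idx] < req:
            raise HorizonError(
                f"genotype {genotype.id}: requirement {req} °Cd unreachable "
                f"within weather horizon ending {dates[-1]}"
            )
        return dates[idx]

    return (
        first_reach(genotype.flowering_requirement),
        first_reach(genotype.maturity_requirement),
    )


def default_locations() -> dict[str, LocationProfile]:
    """Hot/stable vs temperate/variable site profiles (southern hemisphere).

    The phase puts the annual minimum at the start of July and the maximum
    at the turn of the year, so an autumn/winter sowing matures into a
    warming spring and a delayed sowing pushes reproduction into heat.
    """
    return {
        "hotsite": LocationProfile(
            name="hotsite", mean_temp=28.5, amplitude=2.5, phase_day=273.5,
            diurnal_range=14.0, daily_noise_sd=1.5,
        ),
        "tempsite": LocationProfile(
            name="tempsite", mean_temp=17.5, amplitude=9.0, phase_day=273.5,
            diurnal_range=12.0, daily_noise_sd=2.5,
        ),
    }


def default_sowing_dates() -> dict[str, dict[int, Date]]:
    """TOS 1 at the commercial window; TOS 2 delayed +1 month (hot site)
    and +2 months (temperate site)."""
    return {
        "hotsite": {1: Date(2019, 5, 15), 2: Date(2019, 6, 15)},
        "tempsite": {1: Date(2019, 5, 15), 2: Date(2019, 7, 15)},
    }


def default_panel(
    n_genotypes: int = 148,
    n_desi: int = 10,
    seed: int = 0,
    heat_sensitivity_scale: float = 1e-2,
) -> list[GenotypeSpec]:
    """Panel mirroring a diverse elite set: 10 desi / 138 kabuli by default,
    origins split Syria/India/Australia."""
    rng = np.random.default_rng(seed)
    origins = (
        ["syria"] * min(129, n_genotypes)
        + ["india"] * min(10, max(0, n_genotypes - 129))
        + ["australia"] * max(0, n_genotypes - 139)
    )
    if len(origins) < n_genotypes:  # small panels: cycle origins
        origins = [("syria", "india", "australia")[i % 3] for i in range(n_genotypes)]
    panel = []
    for i in range(n_genotypes):
        flowering = float(rng.normal(450.0, 35.0))
        flowering = max(250.0, flowering)
        maturity = flowering + max(250.0, float(rng.normal(550.0, 45.0)))
        panel.append(
            GenotypeSpec(
                id=i + 1,
                type="desi" if i < n_desi else "kabuli",
                origin=origins[i],
                flowering_requirement=flowering,
                maturity_requirement=maturity,
                yield_potential=max(200.0, float(rng.normal(2000.0, 200.0))),
                hsw_potential=max(10.0, float(rng.normal(35.0, 5.0))),
                heat_sensitivity=float(rng.uniform(0.0, 2.0)) * heat_sensitivity_scale,
            )
        )
    return panel


def default_response() -> ResponseModel:
    return ResponseModel()


def plots_to_frame(plots) -> pd.DataFrame:
    """Plot records as a tidy DataFrame (one row per plot)."""
    if isinstance(plots, pd.DataFrame):
        return plots
    return pd.DataFrame(
        {
            "plot_id": [p.plot_id for p in plots],
            "genotype_id": [p.genotype_id for p in plots],
            "location": [p.location for p in plots],
            "tos": [p.tos for p in plots],
            "replicate": [p.replicate for p in plots],
            "sowing_date": [p.sowing_date for p in plots],
            "flowering_date": [p.flowering_date for p in plots],
            "maturity_date": [p.maturity_date for p in plots],
            "yield_g": [p.yield_g for p in plots],
            "hsw_g": [p.hsw_g for p in plots],
            "plot_area_m2": [p.plot_area_m2 for p in plots],
        }
    )


def simulate_trial(
    panel: list[GenotypeSpec],
    locations: dict[str, LocationProfile] | None = None,
    tos_dates: dict[str, dict[int, Date]] | None = None,
    n_reps: int = 2,
    response: ResponseModel | None = None,
    config: ThermalConfig | None = None,
    seed: int = 0,
    n_weather_days: int = 400,
    plot_area_m2: float = 8.0,
) -> tuple[list[PlotRecord], dict[str, pd.DataFrame]]:
    """Simulate a full multi-environment RCBD trial.

    Returns the plot records and the per-location weather series.  One random
    stream drives the run, consumed in a fixed order — weather per location
    (in sorted name order), then genotype/environment/G×E effects, then plot
    noise — so any stage can be regenerated independently.
    """
    if not panel:
        raise ValueError("panel must be non-empty")
    locations = locations or default_locations()
    tos_dates = tos_dates or default_sowing_dates()
    response = response or default_response()
    config = config or ThermalConfig()

    root = np.random.SeedSequence(seed)
    weather_seed, effects_seed, noise_seed = root.spawn(3)

    loc_names = sorted(locations)
    weather: dict[str, pd.DataFrame] = {}
    for sub, name in zip(weather_seed.spawn(len(loc_names)), loc_names):
        start = min(tos_dates[name].values()) - timedelta(days=5)
        weather[name] = generate_weather(
            locations[name], start, n_weather_days,
            seed=int(sub.generate_state(1)[0] % (2**31)),
        )

    envs = [
        (name, tos) for name in loc_names for tos in sorted(tos_dates[name])
    ]
    eff = np.random.default_rng(effects_seed)
    g_yield = eff.normal(0.0, response.yield_genotype_sd, len(panel))
    g_hsw = eff.normal(0.0, response.hsw_genotype_sd, len(panel))
    e_yield = eff.normal(0.0, response.yield_env_sd, len(envs))
    e_hsw = eff.normal(0.0, response.hsw_env_sd, len(envs))
    ge_yield = eff.normal(0.0, response.yield_gxe_sd, (len(panel), len(envs)))
    ge_hsw = eff.normal(0.0, response.hsw_gxe_sd, (len(panel), len(envs)))
    b_yield = eff.normal(0.0, response.yield_block_sd, (len(envs), n_reps))
    b_hsw = eff.normal(0.0, response.hsw_block_sd, (len(envs), n_reps))

    noise = np.random.default_rng(noise_seed)
    records: list[PlotRecord] = []
    for j, (loc, tos) in enumerate(envs):
        sowing = tos_dates[loc][tos]
        wx = weather[loc]
        moderation = response.site_stress_moderation.get(loc, 1.0)
        yield_offset = response.location_yield_offset.get(loc, 0.0)
        hsw_offset = response.location_hsw_offset.get(loc, 0.0)
        for i, genotype in enumerate(panel):
            flowering, maturity = simulate_phenology(genotype, wx, sowing, config)
            sdd = compute_sdd(wx, StageWindow(sowing, maturity), config)
            for rep in range(1, n_reps + 1):
                base_yield = (
                    response.yield_mean
                    + yield_offset
                    + g_yield[i]
                    + e_yield[j]
                    + ge_yield[i, j]
                    + b_yield[j, rep - 1]
                    + noise.normal(0.0, response.yield_residual_sd)
                )
                stress_factor = max(
                    0.0,
                    1.0
                    - genotype.heat_sensitivity
                    * response.sdd_penalty_yield
                    * moderation
                    * sdd,
                )
                yield_g = max(0.0, base_yield * stress_factor)
                hsw_g = (
                    response.hsw_mean
                    + hsw_offset
                    + g_hsw[i]
                    + e_hsw[j]
                    + ge_hsw[i, j]
                    + b_hsw[j, rep - 1]
                    + noise.normal(0.0, response.hsw_residual_sd)
                    - response.sdd_penalty_hsw * sdd
                )
                records.append(
                    PlotRecord(
                        plot_id=f"{loc}-t{tos}-r{rep}-g{genotype.id:03d}",
                        genotype_id=genotype.id,
                        location=loc,
                        tos=tos,
                        replicate=rep,
                        sowing_date=sowing,
                        flowering_date=flowering,
                        maturity_date=maturity,
                        yield_g=yield_g,
                        hsw_g=max(1.0, hsw_g),
                        plot_area_m2=plot_area_m2,
                    )
                )
    return records, weather
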