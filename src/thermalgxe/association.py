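"""Thermal-trait associations: rank correlations and exponential trends.

Spearman's rank correlation relates accumulated GDD/SDD over a growth
period (vegetative, reproductive or full season) to harvest traits across
genotype × environment predicted means, per location.  Yield decline with
accumulated heat is additionally summarised by an exponential trend
y = a·e^{bx}, fitted as a straight line on (x, ln y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import plots_to_frame

__all__ = [
    "CorrelationResult",
    "TrendFit",
    "correlate_thermal_traits",
    "fit_exponential_trend",
    "significance_tier",
    "spearman",
]

TIER_STRONG = 0.001
TIER_WEAK = 0.05


def spearman(x, y) -> tuple[float, float]:
    """Spearman's rho with mid-ranked ties and a t-approximation p-value.

    Equivalent to Pearson correlation of average-ranked data; p is two-sided
    from the t distribution with n−2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant input vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def significance_tier(p_value: float) -> str:
    if math.isnan(p_value):
        return "ns"
    if p_value < TIER_STRONG:
        return "p<0.001"
    if p_value < TIER_WEAK:
        return "p<0.05"
    return "ns"


@dataclass(frozen=True)
class CorrelationResult:
    """One location × growth period × (thermal variate, trait) correlation."""

    location: str
    period: str
    thermal: str  # "gdd" | "sdd"
    trait: str  # "yield_g" | "hsw_g"
    rho: float
    p_value: float
    n: int

    @property
    def tier(self) -> str:
        return significance_tier(self.p_value)


def _mean_level_table(plots, profiles: pd.DataFrame, period: str) -> pd.DataFrame:
    """Genotype × environment means of thermal and harvest variables."""
    frame = plots_to_frame(plots)
    prof = profiles.loc[profiles["stage"] == period]
    if prof.empty:
        raise ValueError(f"no thermal profiles for period {period!r}")
    merged = frame.merge(prof, on="plot_id", validate="one_to_one")
    return (
        merged.groupby(["location", "tos", "genotype_id"], sort=True)[
            ["gdd", "sdd", "yield_g", "hsw_g"]
        ]
        .mean()
        .reset_index()
    )


def correlate_thermal_traits(
    plots,
    profiles: pd.DataFrame,
    periods=("vegetative", "reproductive"),
    traits=("yield_g", "hsw_g"),
) -> list[CorrelationResult]:
    """Spearman correlations of GDD/SDD with harvest traits, per location.

    Computed on genotype × environment predicted means, pooling times of
    sowing within each location.  A constant thermal variate (e.g. zero SDD
    throughout a mild period) yields NaN rho/p reported as "ns".
    """
    results: list[CorrelationResult] = []
    for period in periods:
        means = _mean_level_table(plots, profiles, period)
        for loc, grp in means.groupby("location", sort=True):
            for thermal in ("gdd", "sdd"):
                for trait in traits:
                    try:
                        rho, p = spearman(grp[thermal], grp[trait])
                    except ValueError:
                        rho, p = float("nan"), float("nan")
                    results.append(
                        CorrelationResult(
                            location=loc,
                            period=period,
                            thermal=thermal,
                            trait=trait,
                            rho=rho,
                            p_value=p,
                            n=len(grp),
                        )
                    )
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "location": [r.location for r in results],
            "period": [r.period for r in results],
            "thermal": [r.thermal for r in results],
            "trait": [r.trait for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
            "tier": [r.tier for r in results],
        }
    )


@dataclass(frozen=True)
class TrendFit:
    """Exponential trend y = a·e^{bx} fitted on the log scale."""

    a: float
    b: float
    r2: float

    def predict(self, x) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, float))

    def summary(self) -> str:
        return f"y = {self.a:.4g}·exp({self.b:.4g}·x), R² = {self.r2:.3f}"


def fit_exponential_trend(x, y, r2_scale: str = "log") -> TrendFit:
    """Least-squares exponential trend via linear regression of ln y on x.

    ``r2_scale``: "log" computes R² on the log scale where the model is
    linear (default); "original" computes it against y directly.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be 1-d, equal length >= 3")
    if (y <= 0).any():
        raise ValueError("exponential trend requires strictly positive y")
    if r2_scale not in {"log", "original"}:
        raise ValueError(f"unknown r2_scale {r2_scale!r}")
    ln_y = np.log(y)
    b, ln_a = np.polyfit(x, ln_y, 1)
    a = float(np.exp(ln_a))
    if r2_scale == "log":
        fitted = ln_a + b * x
        ss_res = float(((ln_y - fitted) ** 2).sum())
        ss_tot = float(((ln_y - ln_y.mean()) ** 2).sum())
    else:
        fitted = a * np.exp(b * x)
        ss_res = float(((y - fitted) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return TrendFit(a=a, b=float(b), r2=max(0.0, min(1.0, r2)))
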