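"""Trial summaries: predicted genotype means, environment tables, and the
relative-difference percentage used to compare environments.

An *environment* throughout is a location × time-of-sowing combination.
Predicted means are replicate means adjusted for block effects, the balanced
stand-in for a designed-experiment mixed-model fit; under a balanced RCBD
the adjustment cancels and they equal plain replicate means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import plots_to_frame

__all__ = [
    "GxETable",
    "environment_summary",
    "predicted_means",
    "relative_difference",
    "yield_t_ha",
]

#: grams per m² -> tonnes per hectare
G_PER_M2_TO_T_PER_HA = 0.01


def yield_t_ha(yield_g, plot_area_m2) -> float:
    """Plot yield in tonnes/hectare from grams and plot area (m²)."""
    return np.asarray(yield_g, float) / np.asarray(plot_area_m2, float) * G_PER_M2_TO_T_PER_HA


@dataclass
class GxETable:
    """Genotype × environment matrix of predicted trait means.

    ``data`` has genotype ids as the index and environment labels as
    columns; no missing cells are allowed.
    """

    trait: str
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = [
                (g, e)
                for g in self.data.index
                for e in self.data.columns
                if pd.isna(self.data.loc[g, e])
            ]
            raise ValueError(f"GxE table for {self.trait} has missing cells: {bad[:10]}")

    @property
    def n_genotypes(self) -> int:
        return self.data.shape[0]

    @property
    def n_environments(self) -> int:
        return self.data.shape[1]


def env_label(location: str, tos: int) -> str:
    return f"{location}-tos{tos}"


def predicted_means(plots, trait: str, by: str = "location_tos") -> GxETable:
    """Block-adjusted genotype × environment means for one trait.

    Each observation is adjusted by its block's deviation from the
    environment mean (block effect = block mean − environment mean), then
    averaged over replicates.  With balanced data this equals the raw
    replicate mean.

    ``by``: ``"location_tos"`` treats each location × TOS as an environment;
    ``"tos_within:<location>"`` restricts to one location with TOS as the
    environment axis (the layout used for stability runs).
    """
    frame = plots_to_frame(plots).copy()
    if by == "location_tos":
        frame["env"] = [
            env_label(l, t) for l, t in zip(frame["location"], frame["tos"])
        ]
    elif by.startswith("tos_within:"):
        loc = by.split(":", 1)[1]
        frame = frame.loc[frame["location"] == loc].copy()
        if frame.empty:
            raise ValueError(f"no plots for location {loc!r}")
        frame["env"] = [f"tos{t}" for t in frame["tos"]]
    else:
        raise ValueError(f"unknown grouping {by!r}")

    env_mean = frame.groupby("env")[trait].transform("mean")
    block_mean = frame.groupby(["env", "replicate"])[trait].transform("mean")
    frame["_adj"] = frame[trait] - (block_mean - env_mean)
    table = frame.pivot_table(
        index="genotype_id", columns="env", values="_adj", aggfunc="mean"
    )
    table.columns.name = None
    table.index.name = "genotype_id"

    counts = frame.pivot_table(
        index="genotype_id", columns="env", values=trait, aggfunc="count"
    )
    if table.isna().any().any() or (counts.fillna(0) < 1).any().any():
        missing = [
            (g, e)
            for g in counts.index
            for e in counts.columns
            if not counts.loc[g, e] >= 1
        ]
        raise ValueError(
            f"incomplete genotype × environment layout for {trait}: "
            f"missing cells {missing[:10]}"
        )
    return GxETable(trait=trait, data=table)


def environment_summary(plots, profiles: pd.DataFrame, stage: str = "full_season") -> pd.DataFrame:
    """Per-environment mean ± sd of phenology, thermal and harvest traits.

    ``profiles`` is the long table from :func:`thermalgxe.thermal.profiles_table`
    (plot_id, stage, age_days, grow_days, gdd, sdd).  Yield is reported in
    t/ha using each plot's area.  One row per (location, tos) with columns
    ``<var>_mean`` / ``<var>_sd``; sd is the sample standard deviation.
    """
    frame = plots_to_frame(plots).copy()
    prof = profiles.loc[profiles["stage"] == stage]
    if prof.empty:
        raise ValueError(f"no thermal profiles for stage {stage!r}")
    merged = frame.merge(prof, on="plot_id", how="left", validate="one_to_one")
    if merged[["gdd", "sdd", "age_days", "grow_days"]].isna().any().any():
        missing = merged.loc[merged["gdd"].isna(), "plot_id"].tolist()
        raise ValueError(f"thermal profiles missing for plots: {missing[:10]}")
    merged["yield_t_ha"] = yield_t_ha(merged["yield_g"], merged["plot_area_m2"])

    rows = []
    for (loc, tos), grp in merged.groupby(["location", "tos"], sort=True):
        row = {"location": loc, "tos": tos, "stage": stage, "n_plots": len(grp)}
        for var in ("age_days", "grow_days", "gdd", "sdd", "yield_t_ha", "hsw_g"):
            row[f"{var}_mean"] = float(grp[var].mean())
            row[f"{var}_sd"] = float(grp[var].std(ddof=1)) if len(grp) > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def relative_difference(a: float, b: float) -> float:
    """Percentage difference relative to the larger value.

    ``(max(a,b) − min(a,b)) / max(a,b) × 100`` — symmetric and bounded in
    [0, 100) for positive inputs.  This is the convention behind every
    "X% larger / faster / variation" comparison the package reports; note it
    differs from the more common (max−min)/min form.
    """
    hi, lo = (a, b) if a >= b else (b, a)
    if hi <= 0:
        raise ValueError("relative_difference undefined unless max(a, b) > 0")
    return (hi - lo) / hi * 100.0
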