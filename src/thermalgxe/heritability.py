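"""Broad-sense heritability from balanced RCBD variance components.

Within one environment a balanced randomized complete block design with g
genotypes and r blocks decomposes as

    y_ik = mu + g_i + b_k + e_ik

The method-of-moments (expected mean squares) solution gives

    s_e² = MS_error
    s_g² = max(0, (MS_genotype − MS_error) / r)

and broad-sense heritability on a genotype-mean basis

    H² = s_g² / (s_g² + s_e²/r)

which is the fraction of variance among genotype means attributable to
genetic variance.  The estimator requires balance (equal replicate counts);
it is unbiased for the variance components before the truncation at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import plots_to_frame

__all__ = [
    "HeritabilityResult",
    "broad_sense_heritability",
    "heritability_by_environment",
    "variance_components_rcbd",
]


class BalanceError(ValueError):
    """Replicate counts differ across genotypes; the EMS estimator is invalid."""


def variance_components_rcbd(plots, trait: str) -> tuple[float, float]:
    """Genetic and residual variance components (s_g², s_e²) for one trait.

    ``plots`` must come from a single environment: one observation per
    genotype × replicate, every genotype in every block.
    """
    frame = plots_to_frame(plots)
    counts = frame.groupby("genotype_id")["replicate"].count()
    r = int(counts.iloc[0])
    if (counts != r).any() or r < 2:
        raise BalanceError(
            "RCBD estimator needs the same replicate count (>= 2) for every "
            f"genotype; got counts {sorted(counts.unique())}"
        )
    block_counts = frame.groupby("replicate")["genotype_id"].nunique()
    g = frame["genotype_id"].nunique()
    if (block_counts != g).any():
        raise BalanceError("each block must contain every genotype exactly once")

    y = frame.pivot_table(index="genotype_id", columns="replicate", values=trait)
    Y = y.to_numpy(float)
    grand = Y.mean()
    ss_genotype = r * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_block = g * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_error = max(0.0, ss_total - ss_genotype - ss_block)  # round-off guard
    ms_genotype = ss_genotype / (g - 1)
    ms_error = ss_error / ((g - 1) * (r - 1))
    s_e2 = float(ms_error)
    s_g2 = float(max(0.0, (ms_genotype - ms_error) / r))
    return s_g2, s_e2


def broad_sense_heritability(s_g2: float, s_e2: float, r: int) -> float:
    """H² = s_g² / (s_g² + s_e²/r), on the genotype-mean basis."""
    if s_g2 < 0 or s_e2 < 0:
        raise ValueError("variance components must be non-negative")
    if r < 1:
        raise ValueError("replicate count must be >= 1")
    if s_g2 == 0 and s_e2 == 0:
        raise ValueError("H² undefined when both variance components are zero")
    return s_g2 / (s_g2 + s_e2 / r)


@dataclass(frozen=True)
class HeritabilityResult:
    """Variance components and H² for one trait in one environment."""

    trait: str
    environment: str
    s_g2: float
    s_e2: float
    r: int
    h2: float

    def summary(self) -> str:
        return (
            f"{self.trait} @ {self.environment}: "
            f"s_g²={self.s_g2:.4g}, s_e²={self.s_e2:.4g}, r={self.r}, "
            f"H²={self.h2:.3f}"
        )


def heritability_by_environment(plots, traits=("yield_g", "hsw_g")) -> list[HeritabilityResult]:
    """One within-environment model per (location × TOS, trait)."""
    frame = plots_to_frame(plots)
    results = []
    for (loc, tos), grp in frame.groupby(["location", "tos"], sort=True):
        r = int(grp.groupby("genotype_id")["replicate"].count().iloc[0])
        for trait in traits:
            s_g2, s_e2 = variance_components_rcbd(grp, trait)
            results.append(
                HeritabilityResult(
                    trait=trait,
                    environment=f"{loc}-tos{tos}",
                    s_g2=s_g2,
                    s_e2=s_e2,
                    r=r,
                    h2=broad_sense_heritability(s_g2, s_e2, r),
                )
            )
    return results
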