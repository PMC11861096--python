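"""Genotype-by-environment stability statistics and the GGE biplot.

Two complementary rankings over a genotype × environment table of predicted
means:

* cultivar superiority (Lin & Binns): P_i = Σ_j (X_ij − M_j)² / (2n), the
  mean squared distance of genotype i from the best genotype M_j in each of
  the n environments — low values mark broadly superior genotypes;
* static stability: S_i² = Var_j(X_ij), the sample variance of a genotype's
  means across environments — low values mark environment-insensitive
  genotypes.

The GGE biplot removes the environment main effect by centering each
environment column and decomposes what remains (genotype main effect plus
G×E interaction) by SVD; PC percentages partition that variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .summaries import GxETable

__all__ = [
    "BiplotResult",
    "StabilityResult",
    "gge_decompose",
    "rank_and_select",
    "stability_table",
    "static_stability",
    "superiority",
    "top_k_overlap",
]


def _check_table(table: GxETable) -> pd.DataFrame:
    if table.n_environments < 2:
        raise ValueError("stability statistics need at least 2 environments")
    return table.data


def superiority(table: GxETable) -> pd.Series:
    """Lin–Binns cultivar superiority coefficient per genotype (lower = better)."""
    data = _check_table(table)
    best = data.max(axis=0)
    p = ((data - best) ** 2).sum(axis=1) / (2 * table.n_environments)
    p.name = "superiority"
    return p


def static_stability(table: GxETable) -> pd.Series:
    """Across-environment sample variance per genotype (lower = more stable)."""
    data = _check_table(table)
    s2 = data.var(axis=1, ddof=1)
    s2.name = "static_stability"
    return s2


def rank_and_select(coefficients: pd.Series, k: int) -> tuple[pd.Series, list]:
    """Ascending ranks (1 = best, i.e. lowest coefficient) and the top-k ids.

    Ties are broken by genotype id so rankings are reproducible.
    """
    if k > len(coefficients):
        raise ValueError(f"k={k} exceeds number of genotypes {len(coefficients)}")
    order = sorted(coefficients.index, key=lambda g: (coefficients[g], g))
    ranks = pd.Series(
        {g: r for r, g in enumerate(order, start=1)}, name="rank"
    ).reindex(coefficients.index)
    return ranks, order[:k]


def top_k_overlap(top_a, top_b) -> float:
    """Fraction of one top-k list shared with another (|A ∩ B| / k)."""
    if len(top_a) != len(top_b):
        raise ValueError("top-k sets must have equal size")
    if not top_a:
        raise ValueError("top-k sets must be non-empty")
    return len(set(top_a) & set(top_b)) / len(top_a)


@dataclass
class StabilityResult:
    """Superiority and static-stability coefficients with ranks, one trait."""

    trait: str
    table: pd.DataFrame  # genotype_id, superiority, static_stability, ranks

    def top(self, metric: str = "superiority", k: int = 10) -> list:
        col = f"rank_{'superiority' if metric == 'superiority' else 'static'}"
        return list(self.table.sort_values(col).head(k)["genotype_id"])


def stability_table(table: GxETable) -> StabilityResult:
    """Both stability statistics, ranked, as one tidy frame."""
    sup = superiority(table)
    stat = static_stability(table)
    rank_sup, _ = rank_and_select(sup, k=len(sup))
    rank_stat, _ = rank_and_select(stat, k=len(stat))
    frame = pd.DataFrame(
        {
            "genotype_id": sup.index,
            "superiority": sup.values,
            "static_stability": stat.values,
            "rank_superiority": rank_sup.values,
            "rank_static": rank_stat.values,
        }
    ).reset_index(drop=True)
    return StabilityResult(trait=table.trait, table=frame)


@dataclass
class BiplotResult:
    """Rank-2 GGE decomposition of an environment-centered G×E table."""

    trait: str
    genotype_scores: pd.DataFrame  # index genotype ids, columns PC1/PC2
    environment_scores: pd.DataFrame  # index environment labels
    pc_variance_pct: tuple[float, float]
    scaling: str
    singular_values: np.ndarray = field(repr=False, default=None)
    explained_variance_pct: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False

    def summary(self) -> str:
        pc1, pc2 = self.pc_variance_pct
        lines = [
            f"GGE biplot — {self.trait} ({self.scaling} scaling)",
            f"  PC1: {pc1:.2f}%  PC2: {pc2:.2f}%  (sum {pc1 + pc2:.2f}%)",
            f"  {len(self.genotype_scores)} genotypes × "
            f"{len(self.environment_scores)} environments",
        ]
        if self.degenerate:
            lines.append("  [degenerate: centered table has zero variance]")
        return "\n".join(lines)


def gge_decompose(table: GxETable, scaling: str = "symmetric") -> BiplotResult:
    """Environment-centered SVD of a G×E table (the GGE biplot).

    Columns are centered by their environment mean, removing the environment
    main effect while retaining genotype and G×E signal; the centered matrix
    is decomposed as UΣVᵀ.  ``pc_variance_pct`` gives σ_k²/Σσ² × 100 for the
    first two axes.  Axis signs follow the convention that the largest-
    magnitude genotype loading on each axis is positive, making output
    deterministic.  Scalings: ``symmetric`` (both sides get √σ),
    ``genotype_focused`` (UΣ, V), ``environment_focused`` (U, VΣ).
    """
    if scaling not in {"symmetric", "genotype_focused", "environment_focused"}:
        raise ValueError(f"unknown scaling {scaling!r}")
    if table.n_genotypes < 3 or table.n_environments < 2:
        raise ValueError("GGE needs >= 3 genotypes and >= 2 environments")
    data = table.data
    centered = data - data.mean(axis=0)
    X = centered.to_numpy(float)

    total = float((X**2).sum())
    if total == 0.0:
        zeros_g = pd.DataFrame(0.0, index=data.index, columns=["PC1", "PC2"])
        zeros_e = pd.DataFrame(0.0, index=data.columns, columns=["PC1", "PC2"])
        return BiplotResult(
            trait=table.trait,
            genotype_scores=zeros_g,
            environment_scores=zeros_e,
            pc_variance_pct=(0.0, 0.0),
            scaling=scaling,
            singular_values=np.zeros(min(X.shape)),
            explained_variance_pct=np.zeros(min(X.shape)),
            degenerate=True,
        )

    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # sign convention: largest-|u| entry on each axis made positive
    for k in range(u.shape[1]):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] *= -1
            vt[k, :] *= -1

    explained = s**2 / (s**2).sum() * 100.0
    k2 = min(2, len(s))
    if scaling == "symmetric":
        g = u[:, :k2] * np.sqrt(s[:k2])
        e = vt[:k2, :].T * np.sqrt(s[:k2])
    elif scaling == "genotype_focused":
        g = u[:, :k2] * s[:k2]
        e = vt[:k2, :].T
    else:
        g = u[:, :k2]
        e = vt[:k2, :].T * s[:k2]
    cols = ["PC1", "PC2"][:k2]
    return BiplotResult(
        trait=table.trait,
        genotype_scores=pd.DataFrame(g, index=data.index, columns=cols),
        environment_scores=pd.DataFrame(e, index=data.columns, columns=cols),
        pc_variance_pct=(
            float(explained[0]),
            float(explained[1]) if len(explained) > 1 else 0.0,
        ),
        scaling=scaling,
        singular_values=s,
        explained_variance_pct=explained,
    )
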