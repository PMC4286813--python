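"""Descriptive root-system-architecture statistics.

Covers the standard phenometrics of lateral-root (LR) assays:

* emerged-LR density — emerged LRs per cm of primary root (PR), per seedling;
* branching density — emerged LRs per cm of the branching zone, the PR
  segment spanning the most shootward to the most rootward emerged LR;
* stage-distribution summaries — the proportion of lateral-root primordia
  (LRPs) at each developmental stage, either from genotype-pooled counts or
  as the mean of per-root percentage vectors;
* the standard error of a proportion, sqrt(p(1-p)/n), used for stage
  error bars;
* pairwise two-sample t-tests on per-root densities (Welch by default).

Proportions are kept on [0, 1] internally; multiply by 100 only for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .data_model import (
    STAGES,
    GenotypeStageTable,
    RootObservation,
    ValidationError,
)

__all__ = [
    "DensitySummary",
    "StageDistribution",
    "lr_density",
    "branching_density",
    "proportion_se",
    "stage_distribution",
    "compare_densities",
    "density_summaries",
]


@dataclass(frozen=True)
class DensitySummary:
    """Mean ± SE of a per-root density metric for one genotype."""

    genotype: str
    mean_density: float
    se: float
    n: int
    metric: Literal["whole_root", "branching_zone"]


@dataclass(frozen=True)
class StageDistribution:
    """Per-stage LRP proportions with per-level standard errors.

    ``basis="pooled_counts"`` treats the genotype's pooled counts as one
    multinomial sample (``n`` = pooled LRP count, SEs from the proportion
    formula).  ``basis="per_root_mean"`` averages each root's own percentage
    vector (``n`` = number of roots, SEs are standard errors of the mean
    across roots).
    """

    genotype: str
    proportions: tuple[float, ...]
    se_per_level: tuple[float, ...]
    basis: Literal["pooled_counts", "per_root_mean"]
    n: int

    def early_fraction(self) -> float:
        """Total proportion at early stages I–IV."""
        return sum(p for s, p in zip(STAGES, self.proportions) if s in {"I", "II", "III", "IV"})

    def late_fraction(self) -> float:
        """Total proportion at late stages (VII and emerged)."""
        return sum(p for s, p in zip(STAGES, self.proportions) if s in {"VII", "E"})

    def plot(self, ax=None, percent: bool = True, **bar_kw):
        """Bar chart of the stage distribution with SE error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        scale = 100.0 if percent else 1.0
        y = [p * scale for p in self.proportions]
        yerr = [s * scale for s in self.se_per_level]
        ax.bar(range(len(STAGES)), y, yerr=yerr, capsize=3, **bar_kw)
        ax.set_xticks(range(len(STAGES)), STAGES)
        ax.set_xlabel("LRP developmental stage")
        ax.set_ylabel("% of LRPs" if percent else "proportion of LRPs")
        ax.set_title(self.genotype)
        return ax


def lr_density(emerged_count: int, pr_length_cm: float) -> float:
    """Emerged-LR density: emerged LRs per cm of primary root, per seedling."""
    if not pr_length_cm > 0:
        raise ValidationError(f"pr_length_cm must be positive, got {pr_length_cm}")
    if emerged_count < 0:
        raise ValidationError("emerged_count must be nonnegative")
    return emerged_count / pr_length_cm


def branching_density(lr_positions_cm: Sequence[float], emerged_count: int) -> float:
    """Emerged-LR density per cm of the PR branching zone.

    The branching zone spans from the first (most shootward) to the last
    (most rootward) emerged LR; with fewer than two LRs it has zero extent
    and the metric is undefined.
    """
    if emerged_count < 2:
        raise ValidationError(
            "branching density is undefined for fewer than 2 emerged LRs "
            "(branching zone has zero extent)"
        )
    if len(lr_positions_cm) != emerged_count:
        raise ValidationError(
            f"got {len(lr_positions_cm)} positions for emerged_count={emerged_count}"
        )
    span = max(lr_positions_cm) - min(lr_positions_cm)
    if span <= 0:
        raise ValidationError("branching zone has zero extent (coincident LR positions)")
    return emerged_count / span


def proportion_se(p: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if not 0.0 <= p <= 1.0:
        raise ValidationError(f"p must lie in [0, 1], got {p}")
    if n < 1:
        raise ValidationError(f"n must be a positive integer, got {n}")
    return math.sqrt(p * (1.0 - p) / n)


def stage_distribution(
    table: GenotypeStageTable,
    basis: Literal["pooled_counts", "per_root_mean"] = "pooled_counts",
    per_root: Sequence[RootObservation] | None = None,
) -> StageDistribution:
    """Summarise a genotype's LRP stage distribution.

    Parameters
    ----------
    table
        The genotype's pooled stage counts.
    basis
        ``"pooled_counts"`` — proportions are pooled counts / pooled total,
        with SEs from :func:`proportion_se` at n = pooled total.
        ``"per_root_mean"`` — proportions are the mean of per-root percentage
        vectors (each root weighted equally), with SEs the standard error of
        that mean across roots; requires ``per_root``.
    per_root
        The genotype's individual root observations (``per_root_mean`` only);
        roots with zero scored LRPs are excluded from the average since their
        percentage vector is undefined.
    """
    if basis == "pooled_counts":
        n = table.pooled.n
        if n == 0:
            raise ValidationError(
                f"genotype {table.genotype!r}: zero pooled LRPs, stage distribution degenerate"
            )
        props = table.pooled.as_array() / n
        ses = tuple(proportion_se(float(p), n) for p in props)
        return StageDistribution(
            genotype=table.genotype,
            proportions=tuple(float(p) for p in props),
            se_per_level=ses,
            basis=basis,
            n=n,
        )
    if basis == "per_root_mean":
        if per_root is None:
            raise ValidationError("per_root observations required for per_root_mean basis")
        vecs = []
        for o in per_root:
            if o.genotype != table.genotype:
                continue
            n_i = o.stage_counts.n
            if n_i == 0:
                continue
            vecs.append(o.stage_counts.as_array() / n_i)
        if not vecs:
            raise ValidationError(
                f"genotype {table.genotype!r}: no roots with scored LRPs for per_root_mean"
            )
        mat = np.vstack(vecs)
        mean = mat.mean(axis=0)
        if mat.shape[0] > 1:
            sem = mat.std(axis=0, ddof=1) / math.sqrt(mat.shape[0])
        else:
            sem = np.zeros(len(STAGES))
        return StageDistribution(
            genotype=table.genotype,
            proportions=tuple(float(p) for p in mean),
            se_per_level=tuple(float(s) for s in sem),
            basis=basis,
            n=mat.shape[0],
        )
    raise ValidationError(f"unknown basis {basis!r}")


def compare_densities(
    group_a: Sequence[float],
    group_b: Sequence[float],
    welch: bool = True,
) -> tuple[float, float, float]:
    """Two-sample t-test on per-root densities.

    Returns ``(t, df, p)`` with a two-sided p-value.  Welch's unequal-variance
    test is the default; set ``welch=False`` for Student's pooled-variance
    variant.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        raise ValidationError("both groups have zero variance; t-test undefined")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)


def density_summaries(
    observations: Sequence[RootObservation],
    metric: Literal["whole_root", "branching_zone"] = "whole_root",
) -> list[DensitySummary]:
    """Per-genotype mean ± SE of a density metric over individual roots.

    For ``branching_zone``, roots with fewer than two emerged LRs (for which
    the metric is undefined) are excluded; for ``whole_root`` every root
    contributes, including zero-LR roots.
    """
    values: dict[str, list[float]] = {}
    for o in observations:
        if metric == "whole_root":
            d = lr_density(o.emerged_count, o.pr_length_cm)
        elif metric == "branching_zone":
            if o.emerged_count < 2 or o.lr_positions_cm is None:
                continue
            d = branching_density(o.lr_positions_cm, o.emerged_count)
        else:
            raise ValidationError(f"unknown metric {metric!r}")
        values.setdefault(o.genotype, []).append(d)
    out = []
    for g in sorted(values):
        v = np.asarray(values[g])
        se = float(v.std(ddof=1) / math.sqrt(v.size)) if v.size > 1 else 0.0
        out.append(
            DensitySummary(genotype=g, mean_density=float(v.mean()), se=se, n=v.size, metric=metric)
        )
    return out
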