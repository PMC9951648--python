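"""Descriptive statistics, reliability-tested correlations and marker screening.

The first stages of the prognosis protocol: compute X-bar +- m_x and sigma per
trait and age, estimate Pearson correlations within and between traits across
ontogenesis, flag correlations as *reliable* when r exceeds its error by the
critical t value, and screen the birth-time candidate markers against the
slaughter indices.

The error of a correlation coefficient uses the classical zootechnical
formula m_r = (1 - r^2) / sqrt(n - 2), and reliability is the two-sided
Student test of t = r / m_r at n - 2 degrees of freedom.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .herd_data import (
    AGES,
    DEFAULT_MARKERS,
    DEFAULT_TARGETS,
    LIVE_WEIGHT,
    MEASUREMENTS,
    HerdDataset,
    TraitKey,
    subset_by_group,
)

__all__ = [
    "DescriptiveStats",
    "CorrelationEstimate",
    "MarkerSet",
    "InsufficientDataError",
    "DegenerateDataError",
    "describe",
    "correlate",
    "correlation_from_arrays",
    "correlation_table",
    "marker_target_correlations",
    "screen_markers",
    "render_estimate",
]


class InsufficientDataError(ValueError):
    """Too few complete observations for the requested statistic."""


class DegenerateDataError(ValueError):
    """Zero variance makes the correlation undefined."""


@dataclass(frozen=True)
class DescriptiveStats:
    """X-bar +- m_x and sigma for one trait at one age."""

    trait: str
    age_months: Optional[int]
    n: int
    mean: float
    sem: float
    sd: float

    @property
    def key(self) -> TraitKey:
        return (self.trait, self.age_months)


@dataclass(frozen=True)
class CorrelationEstimate:
    trait_x: TraitKey
    trait_y: TraitKey
    n: int
    r: float
    m_r: float
    t_stat: float
    reliable: bool
    alpha: float = 0.05


@dataclass
class MarkerSet:
    """Markers that passed the reliability + threshold screen against every target."""

    markers: list[TraitKey]
    targets: list[str]
    threshold: float
    require_reliable: bool
    estimates: list[CorrelationEstimate]


def describe(dataset: HerdDataset, trait: str, age_months: Optional[int] = None) -> DescriptiveStats:
    """Mean, sd (n-1 denominator) and standard error of one trait at one age."""
    values = dataset.trait_values((trait, age_months)).to_numpy()
    if len(values) < 2:
        raise InsufficientDataError(
            f"need >= 2 values for {trait} at age {age_months}, have {len(values)}"
        )
    n = len(values)
    sd = float(np.std(values, ddof=1))
    return DescriptiveStats(
        trait=trait,
        age_months=age_months,
        n=n,
        mean=float(np.mean(values)),
        sem=sd / math.sqrt(n),
        sd=sd,
    )


def correlation_from_arrays(
    x: np.ndarray,
    y: np.ndarray,
    pair_x: TraitKey,
    pair_y: TraitKey,
    alpha: float = 0.05,
) -> CorrelationEstimate:
    """Pearson r with its error m_r and the reliability verdict.

    m_r = (1 - r^2)/sqrt(n - 2); the estimate is *reliable* when
    t = r/m_r meets the two-sided critical Student value at ``alpha`` with
    n - 2 degrees of freedom. |r| = 1 (m_r = 0) is reliable by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise InsufficientDataError(f"need >= 4 paired observations, have {n}")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise DegenerateDataError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if 1.0 - abs(r) < 1e-12:  # exactly collinear up to rounding noise
        r = math.copysign(1.0, r)
    m_r = (1.0 - r * r) / math.sqrt(n - 2)
    if m_r == 0.0:
        t_stat = math.inf
        reliable = True
    else:
        t_stat = r / m_r
        t_crit = float(stats.t.ppf(1.0 - alpha / 2.0, n - 2))
        reliable = abs(t_stat) >= t_crit
    return CorrelationEstimate(pair_x, pair_y, n, r, m_r, t_stat, reliable, alpha)


def correlate(
    dataset: HerdDataset,
    pair_x: TraitKey,
    pair_y: TraitKey,
    alpha: float = 0.05,
) -> CorrelationEstimate:
    """Correlation between two (trait, age) variables, complete cases only."""
    sx = dataset.trait_values(pair_x)
    sy = dataset.trait_values(pair_y)
    joined = pd.concat({"x": sx, "y": sy}, axis=1).dropna()
    if len(joined) < 4:
        raise InsufficientDataError(
            f"need >= 4 paired observations for {pair_x} vs {pair_y}, have {len(joined)}"
        )
    return correlation_from_arrays(joined["x"], joined["y"], pair_x, pair_y, alpha)


def _group_views(dataset: HerdDataset, grouping: str) -> dict[str, HerdDataset]:
    if grouping == "all":
        return {"all": dataset}
    levels = sorted(dataset.animals[grouping].dropna().unique())
    views = {lvl: subset_by_group(dataset, grouping, lvl) for lvl in levels}
    views["all"] = dataset  # pooled "total by group" column
    return views


def correlation_table(
    dataset: HerdDataset,
    axis: str = "ages",
    grouping: str = "all",
    alpha: float = 0.05,
    ages: Sequence[int] = AGES,
    traits: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Tidy table of pairwise correlations across ages or across measurements.

    ``axis="ages"`` correlates live weight between every pair of ontogenesis
    ages (per group and pooled); ``axis="measurements"`` correlates every pair
    of body measurements within each age. Columns: group, the two (trait,
    age) labels, n, r, m_r, t, reliable and the printed-style rendering.
    """
    rows = []
    views = _group_views(dataset, grouping)
    if axis == "ages":
        pairs = [
            ((LIVE_WEIGHT, a), (LIVE_WEIGHT, b))
            for i, a in enumerate(ages)
            for b in list(ages)[i + 1 :]
        ]
    elif axis == "measurements":
        traits = list(traits or MEASUREMENTS)
        pairs = [
            ((t1, a), (t2, a))
            for a in ages
            for i, t1 in enumerate(traits)
            for t2 in traits[i + 1 :]
        ]
    else:
        raise ValueError(f"axis must be 'ages' or 'measurements', got {axis!r}")

    for level, view in views.items():
        for px, py in pairs:
            try:
                est = correlate(view, px, py, alpha)
            except (InsufficientDataError, DegenerateDataError):
                continue
            rows.append(
                {
                    "group": level,
                    "trait_x": px[0],
                    "age_x": px[1],
                    "trait_y": py[0],
                    "age_y": py[1],
                    "n": est.n,
                    "r": est.r,
                    "m_r": est.m_r,
                    "t": est.t_stat,
                    "reliable": est.reliable,
                    "rendered": render_estimate(est),
                }
            )
    return pd.DataFrame(rows)


def render_estimate(est: CorrelationEstimate) -> str:
    """Printed style: r to 1 decimal, error to 1 significant digit, '*' if reliable."""
    star = " *" if est.reliable else ""
    return f"{est.r:.1f} ± {est.m_r:.1g}{star}"


def marker_target_correlations(
    dataset: HerdDataset,
    candidates: Iterable[TraitKey] = DEFAULT_MARKERS,
    targets: Iterable[str] = DEFAULT_TARGETS,
    alpha: float = 0.05,
) -> list[CorrelationEstimate]:
    """Correlations of every candidate marker with every slaughter target."""
    return [
        correlate(dataset, marker, (target, None), alpha)
        for marker in candidates
        for target in targets
    ]


def screen_markers(
    estimates: Iterable[CorrelationEstimate],
    targets: Iterable[str] = DEFAULT_TARGETS,
    threshold: float = 0.6,
    require_reliable: bool = True,
) -> MarkerSet:
    """Keep markers reliably and highly correlated with *all* targets.

    A marker passes when its correlation with every target is at least
    ``threshold`` and (optionally) flagged reliable. An empty result warns
    rather than raising: a herd may genuinely offer no usable marker.
    """
    targets = list(targets)
    estimates = list(estimates)
    by_marker: dict[TraitKey, dict[str, CorrelationEstimate]] = {}
    for est in estimates:
        by_marker.setdefault(est.trait_x, {})[est.trait_y[0]] = est
    passed = []
    for marker, per_target in by_marker.items():
        if not all(t in per_target for t in targets):
            continue
        ok = all(
            per_target[t].r >= threshold and (per_target[t].reliable or not require_reliable)
            for t in targets
        )
        if ok:
            passed.append(marker)
    if not passed:
        warnings.warn(
            f"no marker passed the screen (threshold={threshold}, "
            f"require_reliable={require_reliable})",
            stacklevel=2,
        )
    return MarkerSet(
        markers=passed,
        targets=targets,
        threshold=threshold,
        require_reliable=require_reliable,
        estimates=estimates,
    )
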