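"""Regression-based forecast tables, multi-marker forecasts and accuracy.

The forecasting rule is the classical indirect-prediction regression: for a
marker x with mean x-bar and a slaughter index y with mean y-bar,

    b = r * sigma_y / sigma_x        (kg of y per unit of x)
    y-hat(x) = y-bar + b * (x - x-bar)

A forecast table tabulates y-hat over a grid of marker values centred on the
marker mean. A per-animal forecast reads one prediction per marker and
combines them as the unweighted arithmetic mean. Forecast accuracy against a
realised slaughter record is 100 * (1 - |forecast - actual| / forecast),
reported at farm level on the mean forecast vs the mean actual.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .biometrics import (
    CorrelationEstimate,
    DescriptiveStats,
    correlate,
    describe,
)
from .herd_data import (
    DEFAULT_MARKERS,
    DEFAULT_TARGETS,
    HerdDataset,
    TraitKey,
    marker_label,
    round_half_up,
)

__all__ = [
    "RegressionCoefficient",
    "GridSpec",
    "ForecastRow",
    "ForecastTable",
    "MarkerForecast",
    "AccuracyReport",
    "regression_coefficient",
    "build_forecast_table",
    "build_tables_from_herd",
    "forecast_animal",
    "forecast_herd",
    "forecast_accuracy",
    "approbate",
]


@dataclass(frozen=True)
class RegressionCoefficient:
    """Slope of a slaughter index on a marker, b = r * sigma_y / sigma_x.

    ``from_slope`` constructs a coefficient from a published slope directly
    (printed-table replication); such instances carry no r or sigmas.
    """

    marker: TraitKey
    target: str
    b: float
    r_used: Optional[float] = None
    sd_target: Optional[float] = None
    sd_marker: Optional[float] = None

    @classmethod
    def from_slope(cls, marker: TraitKey, target: str, b: float) -> "RegressionCoefficient":
        return cls(marker=marker, target=target, b=float(b))


def regression_coefficient(
    stats_marker: DescriptiveStats,
    stats_target: DescriptiveStats,
    corr: CorrelationEstimate,
) -> RegressionCoefficient:
    """Compute b = r * sigma_target / sigma_marker from prior-stage results."""
    pair = {corr.trait_x, corr.trait_y}
    if pair != {stats_marker.key, stats_target.key}:
        raise ValueError(
            f"correlation {corr.trait_x}/{corr.trait_y} does not relate "
            f"{stats_marker.key} and {stats_target.key}"
        )
    if stats_marker.sd == 0.0:
        raise ZeroDivisionError(f"degenerate marker {stats_marker.key}: zero sd")
    b = corr.r * stats_target.sd / stats_marker.sd
    return RegressionCoefficient(
        marker=stats_marker.key,
        target=stats_target.trait,
        b=b,
        r_used=corr.r,
        sd_target=stats_target.sd,
        sd_marker=stats_marker.sd,
    )


@dataclass(frozen=True)
class GridSpec:
    """Marker-value grid: integer-rounded mean +- half_width at ``step``."""

    half_width: float = 6.0
    step: float = 1.0

    def values(self, center: float) -> np.ndarray:
        c = round_half_up(center, 0)
        n = int(round(self.half_width / self.step))
        return c + self.step * np.arange(-n, n + 1)


@dataclass(frozen=True)
class ForecastRow:
    target: str
    b: float
    anchor: float  # target mean: the prediction at the marker mean


@dataclass
class ForecastTable:
    """One marker's forecast table over all predicted slaughter indices."""

    marker: TraitKey
    marker_mean: float
    grid: np.ndarray
    rows: list[ForecastRow]

    def predict(self, target: str, x: float) -> float:
        """Exact affine prediction anchor + b * (x - marker_mean)."""
        row = self._row(target)
        return row.anchor + row.b * (x - self.marker_mean)

    def predict_nearest(self, target: str, x: float) -> float:
        """Prediction at the nearest grid value (table-lookup reading)."""
        if x < self.grid.min() or x > self.grid.max():
            warnings.warn(
                f"marker value {x} outside grid [{self.grid.min()}, {self.grid.max()}] "
                f"for {marker_label(self.marker)}; extrapolating from the line",
                stacklevel=2,
            )
            return self.predict(target, x)
        nearest = float(self.grid[np.argmin(np.abs(self.grid - x))])
        return self.predict(target, nearest)

    def _row(self, target: str) -> ForecastRow:
        for row in self.rows:
            if row.target == target:
                return row
        raise KeyError(f"no forecast row for target {target!r}")

    @property
    def targets(self) -> list[str]:
        return [row.target for row in self.rows]

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        """Printed layout: one row per target, cells over the marker grid."""
        data = {
            "index": [row.target for row in self.rows],
            "regression_coefficient": [round_half_up(row.b, decimals) for row in self.rows],
        }
        frame = pd.DataFrame(data)
        for x in self.grid:
            col = f"{x:g}"
            frame[col] = [round_half_up(self.predict(r.target, float(x)), decimals) for r in self.rows]
        return frame


def build_forecast_table(
    marker_stats: DescriptiveStats,
    targets: Sequence[tuple[DescriptiveStats, RegressionCoefficient]],
    grid: GridSpec = GridSpec(),
) -> ForecastTable:
    """Assemble one marker's forecast table from stage-1/4 results.

    Every coefficient must belong to this marker; each target's anchor is its
    herd mean, so the table predicts the anchor exactly at the marker mean.
    """
    if not targets:
        raise ValueError("no targets supplied")
    rows = []
    for stats_t, coef in targets:
        if coef.marker != marker_stats.key:
            raise ValueError(
                f"coefficient for marker {coef.marker} used in table for {marker_stats.key}"
            )
        if stats_t.trait != coef.target:
            raise ValueError(f"stats for {stats_t.trait} paired with coefficient for {coef.target}")
        rows.append(ForecastRow(target=coef.target, b=coef.b, anchor=stats_t.mean))
    return ForecastTable(
        marker=marker_stats.key,
        marker_mean=marker_stats.mean,
        grid=grid.values(marker_stats.mean),
        rows=rows,
    )


def build_tables_from_herd(
    dataset: HerdDataset,
    markers: Iterable[TraitKey] = DEFAULT_MARKERS,
    targets: Iterable[str] = DEFAULT_TARGETS,
    alpha: float = 0.05,
    grid: GridSpec = GridSpec(),
) -> dict[TraitKey, ForecastTable]:
    """Full stage-4/5 pass: stats, correlations, coefficients, tables."""
    targets = list(targets)
    tables: dict[TraitKey, ForecastTable] = {}
    for marker in markers:
        m_stats = describe(dataset, *marker)
        entries = []
        for target in targets:
            t_stats = describe(dataset, target, None)
            corr = correlate(dataset, marker, (target, None), alpha)
            entries.append((t_stats, regression_coefficient(m_stats, t_stats, corr)))
        tables[marker] = build_forecast_table(m_stats, entries, grid)
    return tables


@dataclass
class MarkerForecast:
    """Per-marker and combined (arithmetic-mean) predictions for one animal."""

    animal_id: Optional[str]
    per_marker: dict[TraitKey, dict[str, float]]
    combined: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        targets = next(iter(self.per_marker.values())).keys()
        self.combined = {
            t: float(np.mean([preds[t] for preds in self.per_marker.values()]))
            for t in targets
        }


def forecast_animal(
    tables: Mapping[TraitKey, ForecastTable] | Sequence[ForecastTable],
    marker_values: Mapping[TraitKey, float],
    interpolation: str = "linear",
    animal_id: Optional[str] = None,
) -> MarkerForecast:
    """Forecast one animal's slaughter indices from its marker values.

    ``interpolation="linear"`` evaluates the regression line exactly (grid
    resolution is then irrelevant); ``"nearest"`` reads the closest printed
    grid cell, as a farmhand would from the paper table.
    """
    if not isinstance(tables, Mapping):
        tables = {t.marker: t for t in tables}
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    per_marker: dict[TraitKey, dict[str, float]] = {}
    for marker, x in marker_values.items():
        table = tables.get(marker)
        if table is None:
            raise KeyError(f"no forecast table for marker {marker_label(marker)}")
        read = table.predict if interpolation == "linear" else table.predict_nearest
        per_marker[marker] = {target: read(target, float(x)) for target in table.targets}
    return MarkerForecast(animal_id=animal_id, per_marker=per_marker)


def forecast_herd(
    tables: Mapping[TraitKey, ForecastTable],
    dataset: HerdDataset,
    markers: Iterable[TraitKey] = DEFAULT_MARKERS,
    interpolation: str = "linear",
) -> pd.DataFrame:
    """Combined forecasts for every animal with complete marker values."""
    wide = dataset.marker_values(markers)
    label_to_key = {marker_label(m): m for m in markers}
    records = []
    for animal_id, row in wide.iterrows():
        mv = {label_to_key[c]: float(row[c]) for c in wide.columns}
        fc = forecast_animal(tables, mv, interpolation, animal_id=str(animal_id))
        records.append({"animal_id": animal_id, **fc.combined})
    return pd.DataFrame(records)


def forecast_accuracy(forecast: float, actual: float) -> float:
    """Accuracy percent: 100 * (1 - |forecast - actual| / forecast).

    Full precision; round with :func:`herd_data.round_half_up` for the
    printed integer percent.
    """
    if forecast <= 0 or actual <= 0:
        raise ValueError(f"forecast and actual must be positive, got {forecast}, {actual}")
    return 100.0 * (1.0 - abs(forecast - actual) / forecast)


@dataclass(frozen=True)
class AccuracyReport:
    """Farm-level forecast-vs-actual comparison for one slaughter index."""

    farm: str
    target: str
    n: int
    forecast_mean: float
    forecast_sem: float
    actual_mean: float
    actual_sem: float
    accuracy_pct: float
    per_animal_accuracy_mean: float

    @property
    def accuracy_rounded(self) -> int:
        return int(round_half_up(self.accuracy_pct, 0))


def approbate(
    train: HerdDataset,
    test: HerdDataset,
    markers: Iterable[TraitKey] = DEFAULT_MARKERS,
    targets: Iterable[str] = DEFAULT_TARGETS,
    external_tables: Optional[Mapping[TraitKey, ForecastTable]] = None,
    alpha: float = 0.05,
    grid: GridSpec = GridSpec(),
) -> list[AccuracyReport]:
    """Out-of-farm validation of the forecast tables.

    Builds tables from ``train`` (or uses ``external_tables``, e.g. another
    farm's), forecasts every ``test`` animal, and per target compares the
    mean forecast against the mean realised slaughter value — the farm-level
    accuracy — alongside the mean of per-animal accuracies.
    """
    markers = list(markers)
    targets = list(targets)
    if test.slaughter.empty:
        raise ValueError("test herd has no slaughter records to approbate against")
    tables = external_tables or build_tables_from_herd(train, markers, targets, alpha, grid)
    forecasts = forecast_herd(tables, test, markers)
    if forecasts.empty:
        raise ValueError("no test animal has complete marker values")
    actual = test.slaughter.set_index("animal_id")
    merged = forecasts.set_index("animal_id").join(actual, how="inner", lsuffix="_fc")
    farm = str(test.provenance.get("farm", "test"))
    reports = []
    for target in targets:
        fc = merged[target + "_fc"]
        ac = merged[target]
        n = len(merged)
        per_animal = np.array([forecast_accuracy(f, a) for f, a in zip(fc, ac)])
        reports.append(
            AccuracyReport(
                farm=farm,
                target=target,
                n=n,
                forecast_mean=float(fc.mean()),
                forecast_sem=float(fc.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                actual_mean=float(ac.mean()),
                actual_sem=float(ac.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0,
                accuracy_pct=forecast_accuracy(float(fc.mean()), float(ac.mean())),
                per_animal_accuracy_mean=float(per_animal.mean()),
            )
        )
    return reports
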