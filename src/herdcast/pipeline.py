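"""End-to-end orchestration of the seven-stage prognosis protocol.

Stages: (1) descriptive statistics, (2) within-trait correlations across
ontogenesis, (3) marker screening against slaughter indices, (4) regression
coefficients, (5) forecast tables, (6) per-animal forecasts + approbation
against realised slaughter records, (7) selection effect and its propagation
to slaughter indices. Each stage writes a delimited artifact so any stage can
be rerun standalone; a JSON manifest records the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .biometrics import correlation_table, describe, marker_target_correlations, screen_markers
from .forecasting import GridSpec, approbate, build_tables_from_herd, forecast_herd
from .herd_data import (
    AGES,
    DEFAULT_MARKERS,
    DEFAULT_TARGETS,
    LIVE_WEIGHT,
    MEASUREMENTS,
    HerdDataset,
    marker_label,
    read_herd,
    write_herd,
)
from .selection import estimate_heritability, propagate_effect, selection_differential, selection_effect
from .synthetic_herd import default_config, generate_herd

logger = logging.getLogger("herdcast")

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``data_dir`` (a directory holding animals/observations/slaughter
    CSVs) or a synthetic herd of ``n_animals`` generated at ``seed``.
    """

    out_dir: Path
    data_dir: Optional[Path] = None
    n_animals: int = 500
    seed: int = 0
    alpha: float = 0.05
    marker_threshold: float = 0.6
    require_reliable: bool = True
    grid_half_width: float = 6.0
    grid_step: float = 1.0
    top_fraction: float = 0.2
    skip_slaughter: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["data_dir"] = None if self.data_dir is None else str(self.data_dir)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    started: float
    finished: float = 0.0
    outputs: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


def _load_or_generate(config: PipelineConfig) -> HerdDataset:
    if config.data_dir is not None:
        d = Path(config.data_dir)
        sl = d / "slaughter.csv"
        return read_herd(d / "animals.csv", d / "observations.csv", sl if sl.exists() else None)
    gen = default_config(n_animals=config.n_animals, seed=config.seed)
    return generate_herd(gen)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, writing artifacts and a manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__, started=time.time())

    def save(stage: str, name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, index=False)
        manifest.outputs[stage] = str(path)
        manifest.row_counts[stage] = len(frame)

    dataset = _load_or_generate(config)
    logger.info("herd loaded: %d animals, %d observations, %d slaughter records",
                dataset.n_animals, len(dataset.observations), len(dataset.slaughter))
    write_herd(dataset, out / "animals.csv", out / "observations.csv", out / "slaughter.csv")
    manifest.outputs["herd"] = str(out / "animals.csv")

    # stage 1: descriptive statistics
    rows = []
    for trait in (LIVE_WEIGHT,) + MEASUREMENTS:
        for age in AGES:
            try:
                s = describe(dataset, trait, age)
            except Exception:
                continue
            rows.append(dataclasses.asdict(s))
    for target in DEFAULT_TARGETS:
        if not dataset.slaughter.empty:
            s = describe(dataset, target, None)
            rows.append(dataclasses.asdict(s))
    save("1_describe", "descriptives.csv", pd.DataFrame(rows))

    # stage 2: correlations across ontogenesis
    ages_tab = correlation_table(dataset, axis="ages", alpha=config.alpha)
    save("2_correlate", "correlations_ages.csv", ages_tab)

    has_slaughter = not dataset.slaughter.empty and not config.skip_slaughter
    grid = GridSpec(config.grid_half_width, config.grid_step)

    if has_slaughter:
        # stage 3: marker screen
        ests = marker_target_correlations(dataset, DEFAULT_MARKERS, DEFAULT_TARGETS, config.alpha)
        marker_set = screen_markers(
            ests, DEFAULT_TARGETS, config.marker_threshold, config.require_reliable
        )
        logger.info("markers passing screen: %s", [marker_label(m) for m in marker_set.markers])
        save(
            "3_screen",
            "markers.csv",
            pd.DataFrame(
                [
                    {
                        "marker": marker_label(e.trait_x),
                        "target": e.trait_y[0],
                        "n": e.n,
                        "r": e.r,
                        "m_r": e.m_r,
                        "reliable": e.reliable,
                        "passed": e.trait_x in marker_set.markers,
                    }
                    for e in ests
                ]
            ),
        )
        markers = marker_set.markers or list(DEFAULT_MARKERS)

        # stages 4-5: coefficients and forecast tables
        tables = build_tables_from_herd(dataset, markers, DEFAULT_TARGETS, config.alpha, grid)
        coef_rows = [
            {"marker": marker_label(m), "target": row.target, "b": row.b, "anchor": row.anchor}
            for m, tab in tables.items()
            for row in tab.rows
        ]
        save("4_regression", "regression_coefficients.csv", pd.DataFrame(coef_rows))
        table_frames = []
        for m, tab in tables.items():
            f = tab.to_frame()
            f.insert(0, "marker", marker_label(m))
            f.insert(1, "marker_mean", tab.marker_mean)
            table_frames.append(f)
        save("5_tables", "forecast_tables.csv", pd.concat(table_frames, ignore_index=True))

        # stage 6: forecasts + self-approbation
        forecasts = forecast_herd(tables, dataset, markers)
        save("6_forecast", "forecasts.csv", forecasts)
        reports = approbate(dataset, dataset, markers, DEFAULT_TARGETS, external_tables=tables)
        save(
            "6_approbate",
            "accuracy.csv",
            pd.DataFrame([dataclasses.asdict(r) | {"accuracy_rounded": r.accuracy_rounded} for r in reports]),
        )
    else:
        manifest.skipped += ["3_screen", "4_regression", "5_tables", "6_forecast", "6_approbate"]
        logger.warning("no slaughter records (or skipped): stages 3-6 omitted")

    # stage 7: selection effect on birth weight, propagated to slaughter indices
    try:
        h2 = estimate_heritability(dataset, LIVE_WEIGHT, 0, config.alpha)
        diff = selection_differential(dataset, LIVE_WEIGHT, 0, top_fraction=config.top_fraction)
        eff = selection_effect(diff, h2)
        sel_rows = [
            {
                "trait": eff.trait,
                "differential": eff.selection_differential,
                "h2": eff.h2_used,
                "effect_per_generation": eff.effect_per_generation,
                "target": "",
                "b": "",
            }
        ]
        if has_slaughter:
            from .biometrics import correlate
            from .forecasting import regression_coefficient

            m_stats = describe(dataset, LIVE_WEIGHT, 0)
            for target in DEFAULT_TARGETS:
                t_stats = describe(dataset, target, None)
                corr = correlate(dataset, (LIVE_WEIGHT, 0), (target, None), config.alpha)
                b = regression_coefficient(m_stats, t_stats, corr)
                prop = propagate_effect(eff, b)
                sel_rows.append(
                    {
                        "trait": eff.trait,
                        "differential": eff.selection_differential,
                        "h2": eff.h2_used,
                        "effect_per_generation": prop.effect_target,
                        "target": prop.target,
                        "b": prop.b_target_on_source,
                    }
                )
        save("7_selection", "selection_effects.csv", pd.DataFrame(sel_rows))
    except Exception as exc:  # selection stage is advisory when data are thin
        manifest.skipped.append("7_selection")
        logger.warning("selection stage skipped: %s", exc)

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
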