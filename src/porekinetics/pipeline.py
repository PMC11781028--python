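"""End-to-end orchestration: simulate → segment → detect → quantify → fit.

Kept as plain functions so each stage stays independently runnable from the
previous stage's on-disk output (the CLI exposes them as subcommands); the
full-pipeline entry point also powers reproducibility checks via a run
manifest with per-stage checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .trace_io import Trace, analysis_windows
from .synthetic_data import SimulationConfig, GroundTruth, generate_experiment
from .event_detection import (
    estimate_baseline,
    detect_events,
    events_to_table,
    lowpass_filter,
)
from .population_analysis import (
    Boundaries,
    ProbabilitySeries,
    probability_series,
)
from .kinetics import KineticFit, fit_initial_velocity, classify_condition

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisSettings",
    "RunManifest",
    "detect_all",
    "run_experiment",
    "run_pipeline",
]


@dataclass(frozen=True)
class AnalysisSettings:
    """All analysis thresholds, defaulting to the assay's published values."""

    n_sigma: float = 10.0
    merge_gap_ms: float = 0.1
    polarity: int = 1
    dwell_mode: str = "fwhm"
    lowpass_hz: Optional[float] = None  # e.g. 20_000.0 to mirror the amplifier
    window_origin: str = "sweep"  # seconds 4-9 of the waveform period
    boundary_fraction: float = 0.1
    source_minute: int = 1
    min_events: int = 10
    grid_points: int = 512
    peak_mode: str = "highest_amplitude"
    expected_region: Optional[tuple[float, float]] = None
    reference_peak: Optional[float] = None  # explicit boundaries (nA) if set
    fit_window: tuple[float, float] = (1, 15)
    inactive_above: float = -0.1
    active_below: float = -1.0


def detect_all(trace: Trace, settings: AnalysisSettings = AnalysisSettings()):
    """Detect events in every per-sweep analysis window of a trace.

    Baselines are estimated per window (sweep-to-sweep drift is expected in
    real recordings).  Returns the tidy event table.
    """
    if settings.lowpass_hz is not None:
        trace = lowpass_filter(trace, settings.lowpass_hz)
    windows = analysis_windows(trace, origin=settings.window_origin)
    events = []
    for w in windows:
        samples = trace.current[w.start : w.stop]
        baseline = estimate_baseline(samples)
        events.extend(
            detect_events(
                samples,
                baseline,
                trace.sampling_rate,
                n_sigma=settings.n_sigma,
                merge_gap_ms=settings.merge_gap_ms,
                polarity=settings.polarity,
                window_start_sample=w.start,
                sweep_index=w.sweep_index,
                dwell_mode=settings.dwell_mode,
            )
        )
    return events_to_table(events)


@dataclass
class ExperimentResult:
    """Everything one simulated experiment produces."""

    events: pd.DataFrame
    series: ProbabilitySeries
    fit: KineticFit
    classification: str
    ground_truth: GroundTruth


def run_experiment(
    config: SimulationConfig, settings: AnalysisSettings = AnalysisSettings()
) -> ExperimentResult:
    """Simulate one experiment and push it through the full analysis."""
    trace, gt = generate_experiment(config)
    events = detect_all(trace, settings)
    boundaries = None
    if settings.reference_peak is not None:
        boundaries = Boundaries.from_reference(
            settings.reference_peak, fraction=settings.boundary_fraction
        )
    series = probability_series(
        events,
        total_duration_s=trace.duration,
        boundaries=boundaries,
        source_minute=settings.source_minute,
        boundary_fraction=settings.boundary_fraction,
        expected_region=settings.expected_region,
        min_events=settings.min_events,
        grid_points=settings.grid_points,
        peak_mode=settings.peak_mode,
    )
    fit = fit_initial_velocity(series, window=settings.fit_window)
    label = classify_condition(
        fit, inactive_above=settings.inactive_above, active_below=settings.active_below
    )
    return ExperimentResult(
        events=events, series=series, fit=fit, classification=label, ground_truth=gt
    )


# ---------------------------------------------------------------------------
# manifest-driven pipeline (CLI `run`)
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    """Record of one pipeline run; identical inputs reproduce identical sums."""

    seed: int
    config: dict
    settings: dict
    version: str
    outputs: dict = field(default_factory=dict)  # stage -> path
    checksums: dict = field(default_factory=dict)  # stage -> sha256

    def save(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, default=str))
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    config: SimulationConfig,
    out_dir,
    settings: AnalysisSettings = AnalysisSettings(),
    config_snapshot: Optional[dict] = None,
) -> RunManifest:
    """Run the full pipeline, writing every stage output plus a manifest."""
    from .synthetic_data import write_ground_truth
    from .event_detection import write_events
    from .population_analysis import write_probability_series

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = run_experiment(config, settings)

    paths = {
        "ground_truth": out_dir / "ground_truth.tsv",
        "events": out_dir / "events.tsv",
        "probability": out_dir / "probability.tsv",
        "kinetics": out_dir / "kinetics.json",
    }
    write_ground_truth(result.ground_truth, paths["ground_truth"],
                       fractions_path=out_dir / "true_fractions.tsv")
    write_events(result.events, paths["events"])
    write_probability_series(result.series, paths["probability"])
    fit = result.fit
    paths["kinetics"].write_text(
        json.dumps(
            {
                "slope_pct_per_min": fit.slope,
                "intercept_pct": fit.intercept,
                "stderr_slope": fit.stderr_slope,
                "r_squared": fit.r_squared,
                "rate_pct_per_min": fit.rate,
                "window_min": list(fit.window),
                "n_points": fit.n_points,
                "degenerate": fit.degenerate,
                "classification": result.classification,
            },
            indent=1,
        )
    )
    manifest = RunManifest(
        seed=config.seed,
        config=config_snapshot if config_snapshot is not None else _config_dict(config),
        settings=asdict(settings),
        version=__version__,
        outputs={k: str(v) for k, v in paths.items()},
        checksums={k: _sha256(v) for k, v in paths.items()},
    )
    manifest.save(out_dir / "manifest.json")
    logger.info("pipeline complete: %s", out_dir)
    return manifest


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["species"] = [asdict(s) for s in config.species]
    return d
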