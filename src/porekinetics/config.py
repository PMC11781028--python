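"""YAML configuration mirroring SimulationConfig + AnalysisSettings.

Every key carries units in its name where it matters (``*_ms``, ``*_nA``,
``*_hz``...).  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .trace_io import WaveformSpec
from .synthetic_data import KineticsSpec, SimulationConfig, SpeciesModel
from .pipeline import AnalysisSettings

__all__ = ["load_config", "default_config_text"]

_KEY_MAP = {
    # yaml key -> dataclass field
    "sampling_rate_hz": "sampling_rate",
    "baseline_mean_nA": "baseline_mean",
    "baseline_sigma_nA": "baseline_sigma",
    "capture_rate_per_s": "capture_rate",
}


def _build(cls, data: dict, extra_map: dict | None = None):
    mapping = dict(_KEY_MAP)
    if extra_map:
        mapping.update(extra_map)
    names = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        name = mapping.get(key, key)
        if name not in names:
            raise ValueError(f"unknown {cls.__name__} key: {key!r}")
        kwargs[name] = value
    return cls(**kwargs)


def load_config(path) -> tuple[SimulationConfig, AnalysisSettings]:
    """Load a YAML run configuration.

    Top-level sections: ``simulation`` (with nested ``waveform``,
    ``kinetics`` and a ``species`` list) and optional ``analysis``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    sim = dict(raw.get("simulation", {}))
    wf = _build(WaveformSpec, sim.pop("waveform", {}),
                {"capture_voltage_mV": "capture_voltage",
                 "rest_voltage_mV": "rest_voltage",
                 "capture_duration_s": "capture_duration",
                 "rest_duration_s": "rest_duration"})
    kin = _build(KineticsSpec, sim.pop("kinetics", {}),
                 {"rate_constant_per_min_per_unit": "rate_constant",
                  "start_offset_min": "start_offset"})
    species_raw = sim.pop("species", None)
    fractions = tuple(sim.pop("fractions", ()))
    if species_raw is not None:
        species = tuple(
            _build(SpeciesModel, s,
                   {"amp_mean_nA": "amp_mean", "amp_sd_nA": "amp_sd",
                    "dwell_mean_ms": "dwell_mean", "dwell_sd_ms": "dwell_sd"})
            for s in species_raw
        )
        sim["species"] = species
    if fractions:
        sim["fractions"] = fractions
    config = _build(SimulationConfig, {**sim, "waveform": wf, "kinetics": kin})
    analysis = raw.get("analysis", {})
    if analysis.get("fit_window") is not None:
        analysis["fit_window"] = tuple(analysis["fit_window"])
    if analysis.get("expected_region") is not None:
        analysis["expected_region"] = tuple(analysis["expected_region"])
    settings = _build(AnalysisSettings, analysis,
                      {"reference_peak_nA": "reference_peak",
                       "boundary_frac": "boundary_fraction"})
    return config, settings


def default_config_text() -> str:
    """A commented demo configuration (5-unit multi-turnover digestion)."""
    return """\
# porekinetics run configuration (units in key names)
simulation:
  sampling_rate_hz: 25000        # instrument default is 100000
  baseline_mean_nA: 2.0
  baseline_sigma_nA: 0.01
  capture_rate_per_s: 2.0
  seed: 1
  waveform:
    capture_voltage_mV: -700
    capture_duration_s: 6.0
    rest_voltage_mV: 100
    rest_duration_s: 3.5
    n_loops: 102                 # ~16 min; 190 for a 30 min recording
  species:
    - {name: 3kbp, length_kbp: 3.0, amp_mean_nA: 0.25, amp_sd_nA: 0.025,
       dwell_mean_ms: 0.20, dwell_sd_ms: 0.04}
    - {name: 1.5kbp, length_kbp: 1.5, amp_mean_nA: 0.15, amp_sd_nA: 0.020,
       dwell_mean_ms: 0.15, dwell_sd_ms: 0.03}
  fractions: [1.0, 0.0]
  kinetics:
    model: first_order_multi_turnover
    rate_constant_per_min_per_unit: 0.02
    enzyme_units: 5
    start_offset_min: 1.0
analysis:
  n_sigma: 10
  merge_gap_ms: 0.1
  boundary_frac: 0.1
  source_minute: 1
  fit_window: [1, 15]
"""
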