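"""Trace containers, file I/O and sweep segmentation.

The assay records ionic current through a glass nanopore while a two-level
voltage program alternates between a *rest* phase (+100 mV, DNA pushed away
from the pore) and a *capture* phase (−700 mV, DNA translocates).  One
waveform period (rest + capture) is a *sweep*; translocation analysis uses a
fixed 5 s window inside each sweep (seconds 4–9 of the period, i.e. capture
seconds 0.5–5.5 with the default waveform — the first half second of capture
is treated as settling).

Traces are exchanged either as a TSV/CSV table (``time_s  current_nA
voltage_mV``) with a JSON metadata sidecar, or as an HDF5 container for
speed.  The sampling rate is mandatory metadata and is never guessed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WaveformSpec",
    "Trace",
    "Sweep",
    "AnalysisWindow",
    "read_trace",
    "write_trace",
    "segment_sweeps",
    "analysis_window",
    "analysis_windows",
]


@dataclass(frozen=True)
class WaveformSpec:
    """Two-level voltage program looped throughout a recording.

    Defaults follow the assay protocol: 3.5 s of +100 mV (rest) followed by
    6 s of −700 mV (capture), looped 180–360 times for a 30–60 min recording.
    """

    capture_voltage: float = -700.0  # mV
    capture_duration: float = 6.0  # s
    rest_voltage: float = 100.0  # mV
    rest_duration: float = 3.5  # s
    n_loops: int = 190

    def __post_init__(self) -> None:
        if self.capture_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("waveform phase durations must be positive")
        if self.n_loops < 1:
            raise ValueError("n_loops must be >= 1")

    @property
    def period(self) -> float:
        """Duration of one sweep (rest + capture), in seconds."""
        return self.rest_duration + self.capture_duration

    @property
    def total_duration(self) -> float:
        return self.n_loops * self.period


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled current recording.

    ``current`` is in nA.  The voltage program is carried either as a
    :class:`WaveformSpec` (synthetic and protocol-driven recordings) or as a
    per-sample mV array (``voltage``); at least one is required for sweep
    segmentation.  ``start_time`` is seconds since the start of the
    recording, which itself begins ~1 min after reagent mixing.
    """

    current: np.ndarray
    sampling_rate: float
    waveform: Optional[WaveformSpec] = None
    voltage: Optional[np.ndarray] = None
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        cur = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "current", cur)
        if not np.all(np.isfinite(cur)):
            bad = int(np.flatnonzero(~np.isfinite(cur))[0])
            raise ValueError(f"non-finite current sample at index {bad}")
        if self.voltage is not None:
            v = np.asarray(self.voltage, dtype=float)
            if v.shape != cur.shape:
                raise ValueError("voltage and current must have equal length")
            object.__setattr__(self, "voltage", v)

    @property
    def n_samples(self) -> int:
        return int(self.current.size)

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_samples / self.sampling_rate

    def time(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class Sweep:
    """One waveform period.  All sample ranges are 0-based, half-open."""

    index: int
    start: int  # first sample of the period (onset of the rest phase)
    capture_start: int
    capture_stop: int
    absolute_start: float  # s, relative to start of recording

    def __post_init__(self) -> None:
        if not (self.start <= self.capture_start < self.capture_stop):
            raise ValueError("invalid sweep sample ranges")


@dataclass(frozen=True)
class AnalysisWindow:
    """Per-sweep sample range used for event analysis (seconds 4–9)."""

    sweep_index: int
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty analysis window")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_HDF5_SUFFIXES = {".h5", ".hdf5"}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _waveform_to_dict(w: Optional[WaveformSpec]):
    return None if w is None else asdict(w)


def _waveform_from_dict(d) -> Optional[WaveformSpec]:
    return None if d is None else WaveformSpec(**d)


def write_trace(trace: Trace, path, fmt: Optional[str] = None) -> Path:
    """Write a trace to ``path``.

    ``fmt`` is inferred from the suffix when omitted: ``.h5``/``.hdf5`` uses
    an HDF5 container, anything else the columnar TSV plus a
    ``<name>.meta.json`` sidecar carrying the sampling metadata.
    """
    path = Path(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in _HDF5_SUFFIXES else "columnar"
    meta = {
        "sampling_rate_hz": trace.sampling_rate,
        "start_time_s": trace.start_time,
        "current_units": "nA",
        "voltage_units": "mV",
        "waveform": _waveform_to_dict(trace.waveform),
    }
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("current_nA", data=trace.current)
            if trace.voltage is not None:
                f.create_dataset("voltage_mV", data=trace.voltage)
            f.attrs["metadata"] = json.dumps(meta)
    elif fmt == "columnar":
        t = trace.time()
        cols = {"time_s": t, "current_nA": trace.current}
        if trace.voltage is not None:
            cols["voltage_mV"] = trace.voltage
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False,
                                  float_format="%.17g")
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")
    return path


def read_trace(path, fmt: Optional[str] = None) -> Trace:
    """Read a trace written by :func:`write_trace`.

    A missing sampling rate is a hard error — the rate is physical metadata
    and is never inferred from timestamps alone.  NaN samples raise with the
    offending index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "hdf5" if path.suffix.lower() in _HDF5_SUFFIXES else "columnar"
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs["metadata"])
            current = f["current_nA"][:]
            voltage = f["voltage_mV"][:] if "voltage_mV" in f else None
    elif fmt == "columnar":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"no metadata sidecar {sidecar.name} for {path.name}: "
                "sampling rate unknown and never guessed"
            )
        meta = json.loads(sidecar.read_text())
        table = pd.read_csv(path, sep="\t", float_precision="round_trip")
        current = table["current_nA"].to_numpy()
        voltage = (
            table["voltage_mV"].to_numpy() if "voltage_mV" in table.columns else None
        )
    else:
        raise ValueError(f"unknown trace format: {fmt!r}")
    if "sampling_rate_hz" not in meta or meta["sampling_rate_hz"] in (None, 0):
        raise ValueError(f"{path.name}: sampling_rate_hz missing from metadata")
    return Trace(
        current=current,
        sampling_rate=float(meta["sampling_rate_hz"]),
        waveform=_waveform_from_dict(meta.get("waveform")),
        voltage=voltage,
        start_time=float(meta.get("start_time_s", 0.0)),
    )


# ---------------------------------------------------------------------------
# sweep segmentation
# ---------------------------------------------------------------------------


def _sweeps_from_spec(trace: Trace, spec: WaveformSpec) -> list[Sweep]:
    rate = trace.sampling_rate
    period = int(round(spec.period * rate))
    rest = int(round(spec.rest_duration * rate))
    cap = int(round(spec.capture_duration * rate))
    n_full = trace.n_samples // period
    if n_full == 0:
        raise ValueError(
            "trace shorter than one waveform period: no capture phases found"
        )
    leftover = trace.n_samples - n_full * period
    if leftover:
        logger.info("dropping trailing partial sweep (%d samples)", leftover)
    sweeps = []
    for i in range(n_full):
        start = i * period
        sweeps.append(
            Sweep(
                index=i,
                start=start,
                capture_start=start + rest,
                capture_stop=start + rest + cap,
                absolute_start=trace.start_time + start / rate,
            )
        )
    return sweeps


def _sweeps_from_voltage(trace: Trace) -> list[Sweep]:
    v = trace.voltage
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi - lo < 1.0:  # mV; effectively constant voltage
        raise ValueError("voltage program is constant: no capture phases found")
    # capture = more negative level; threshold halfway between extremes
    mask = v < (lo + hi) / 2.0
    edges = np.flatnonzero(np.diff(mask.astype(np.int8)))
    starts = edges[np.diff(mask.astype(np.int8))[edges] == 1] + 1
    stops = edges[np.diff(mask.astype(np.int8))[edges] == -1] + 1
    if mask[0]:
        starts = np.insert(starts, 0, 0)
    if mask[-1]:
        # trailing capture phase truncated mid-sweep: drop and log
        logger.info("dropping truncated trailing capture phase")
        starts = starts[: len(stops)]
    if len(starts) == 0:
        raise ValueError("no capture phases found in voltage program")
    rate = trace.sampling_rate
    sweeps = []
    prev_stop = 0
    for i, (a, b) in enumerate(zip(starts, stops)):
        sweeps.append(
            Sweep(
                index=i,
                start=int(prev_stop),
                capture_start=int(a),
                capture_stop=int(b),
                absolute_start=trace.start_time + prev_stop / rate,
            )
        )
        prev_stop = b
    return sweeps


def segment_sweeps(trace: Trace) -> list[Sweep]:
    """Split a trace into waveform sweeps (one per capture phase).

    Uses the attached :class:`WaveformSpec` when present (the trace is then
    assumed to start at the onset of a rest phase); otherwise falls back to
    edge detection on the per-sample voltage.  A trailing partial sweep is
    dropped and logged.
    """
    if trace.waveform is not None:
        return _sweeps_from_spec(trace, trace.waveform)
    if trace.voltage is not None:
        return _sweeps_from_voltage(trace)
    raise ValueError("trace has neither a waveform spec nor a voltage array")


def analysis_window(
    sweep: Sweep,
    sampling_rate: float,
    origin: str = "sweep",
    t_start: float = 4.0,
    t_stop: float = 9.0,
) -> AnalysisWindow:
    """Sample range used for event analysis within one sweep.

    With ``origin="sweep"`` (default) the window is seconds ``[4, 9)`` of the
    waveform period, measured from the onset of the rest phase — i.e. capture
    seconds 0.5–5.5 under the default waveform, skipping the first 0.5 s of
    capture as settling.  ``origin="capture"`` measures from the capture
    onset instead; the window must then fit inside the capture phase.
    """
    if origin == "sweep":
        ref = sweep.start
    elif origin == "capture":
        ref = sweep.capture_start
    else:
        raise ValueError(f"unknown window origin {origin!r}")
    start = ref + int(round(t_start * sampling_rate))
    stop = ref + int(round(t_stop * sampling_rate))
    if start < sweep.capture_start or stop > sweep.capture_stop:
        raise ValueError(
            f"analysis window [{t_start}, {t_stop}) s from {origin} start does "
            f"not fit inside the capture phase of sweep {sweep.index}"
        )
    return AnalysisWindow(sweep_index=sweep.index, start=start, stop=stop)


def analysis_windows(
    trace: Trace, sweeps: Optional[Sequence[Sweep]] = None, **kwargs
) -> list[AnalysisWindow]:
    """Convenience: segment sweeps and build every per-sweep window."""
    if sweeps is None:
        sweeps = segment_sweeps(trace)
    return [analysis_window(s, trace.sampling_rate, **kwargs) for s in sweeps]
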