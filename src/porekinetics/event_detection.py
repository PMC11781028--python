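"""Threshold-based detection of conductive translocation pulses.

Events are transient increases in conductance as single dsDNA molecules
translocate.  Within each per-sweep analysis window the baseline is
estimated robustly (median / scaled MAD), a threshold is placed ``n_sigma``
(default 10) standard deviations above the baseline, and each contiguous
supra-threshold excursion — extended to the nearest baseline crossings —
becomes one event.  Peak amplitude is the maximum deviation from the
baseline; dwell time is the full width at half maximum, measured with
sub-sample interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trace_io import Trace

__all__ = [
    "BaselineModel",
    "Event",
    "estimate_baseline",
    "detect_events",
    "events_to_table",
    "write_events",
    "read_events",
    "lowpass_filter",
]

EVENT_COLUMNS = ["sweep", "onset_s", "peak_s", "amp_nA", "dwell_ms", "area_nAms"]


@dataclass(frozen=True)
class BaselineModel:
    """Robust open-pore baseline of one analysis window."""

    mean: float  # nA
    sigma: float  # nA
    method: str = "median_mad"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("baseline sigma must be positive")


@dataclass(frozen=True)
class Event:
    """One translocation pulse."""

    sweep_index: int
    onset_time: float  # s, absolute
    peak_time: float  # s, absolute
    peak_amplitude: float  # nA, deviation from baseline (positive)
    dwell: float  # ms
    area: float  # nA*ms

    def __post_init__(self) -> None:
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")
        if self.peak_amplitude <= 0:
            raise ValueError("peak_amplitude must be positive")


def estimate_baseline(samples: np.ndarray, min_samples: int = 1000) -> BaselineModel:
    """Median / 1.4826·MAD baseline estimate of one analysis window.

    Robust to events occupying up to ~20% of the window.  A degenerate
    (constant) window raises, as no meaningful threshold exists.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size < min_samples:
        raise ValueError(
            f"need at least {min_samples} samples to estimate a baseline, "
            f"got {samples.size}"
        )
    med = float(np.median(samples))
    mad = float(np.median(np.abs(samples - med)))
    sigma = 1.4826 * mad
    if sigma == 0.0:
        raise ValueError("degenerate window: MAD is zero (constant signal?)")
    return BaselineModel(mean=med, sigma=sigma)


def _runs_above(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean array."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(np.int8)))
    return list(zip(idx[0::2], idx[1::2]))


def _half_crossing(dev: np.ndarray, peak: int, half: float, lo: int, hi: int,
                   direction: int) -> float:
    """Fractional index where ``dev`` crosses ``half`` walking from the peak."""
    i = peak
    while lo <= i + direction < hi and dev[i + direction] > half:
        i += direction
    j = i + direction
    if not (lo <= j < hi):
        return float(i)  # clamp at the event extent
    d0, d1 = dev[i], dev[j]
    if d0 == d1:
        return float(i)
    return i + direction * (d0 - half) / (d0 - d1)


def detect_events(
    samples: np.ndarray,
    baseline: BaselineModel,
    sampling_rate: float,
    n_sigma: float = 10.0,
    merge_gap_ms: float = 0.1,
    polarity: int = 1,
    window_start_sample: int = 0,
    sweep_index: int = 0,
    dwell_mode: str = "fwhm",
) -> list[Event]:
    """Detect conductive pulses in one analysis window.

    ``polarity`` is +1 when conductive pulses are positive-going deviations
    from the baseline (the internal normalization), −1 for raw traces where
    increased conductance magnitude appears as a downward deflection.
    Candidate excursions separated by less than ``merge_gap_ms`` are merged
    (split-peak tie-break).  ``dwell_mode`` selects FWHM (default) or the
    width of the threshold crossing (``"threshold"``).
    """
    if dwell_mode not in ("fwhm", "threshold"):
        raise ValueError(f"unknown dwell_mode {dwell_mode!r}")
    samples = np.asarray(samples, dtype=float)
    dev = polarity * (samples - baseline.mean)
    thr = n_sigma * baseline.sigma
    runs = _runs_above(dev > thr)
    if not runs:
        return []

    # merge runs separated by less than the merge gap
    gap = max(1, int(round(merge_gap_ms / 1000.0 * sampling_rate)))
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])

    n = dev.size
    events = []
    for a, b in merged:
        # extend to the nearest baseline crossings (dev <= 0)
        lo = a
        while lo > 0 and dev[lo - 1] > 0:
            lo -= 1
        hi = b
        while hi < n and dev[hi] > 0:
            hi += 1
        seg = dev[lo:hi]
        peak_local = int(np.argmax(seg))
        peak = lo + peak_local
        amp = float(seg[peak_local])
        if dwell_mode == "fwhm":
            left = _half_crossing(dev, peak, amp / 2.0, lo, hi, -1)
            right = _half_crossing(dev, peak, amp / 2.0, lo, hi, +1)
        else:
            left = _half_crossing(dev, peak, thr, lo, hi, -1)
            right = _half_crossing(dev, peak, thr, lo, hi, +1)
        dwell_ms = max(right - left, 0.5) / sampling_rate * 1000.0
        area = float(np.trapezoid(seg, dx=1.0 / sampling_rate)) * 1000.0
        events.append(
            Event(
                sweep_index=sweep_index,
                onset_time=(window_start_sample + lo) / sampling_rate,
                peak_time=(window_start_sample + peak) / sampling_rate,
                peak_amplitude=amp,
                dwell=dwell_ms,
                area=area,
            )
        )
    return events


def events_to_table(events: Sequence[Event]) -> pd.DataFrame:
    """Event list as a tidy table (one row per event)."""
    return pd.DataFrame(
        {
            "sweep": [e.sweep_index for e in events],
            "onset_s": [e.onset_time for e in events],
            "peak_s": [e.peak_time for e in events],
            "amp_nA": [e.peak_amplitude for e in events],
            "dwell_ms": [e.dwell for e in events],
            "area_nAms": [e.area for e in events],
        },
        columns=EVENT_COLUMNS,
    )


def write_events(events, path) -> Path:
    """Write events (list or table) as TSV; lossless round trip."""
    path = Path(path)
    table = events if isinstance(events, pd.DataFrame) else events_to_table(events)
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def read_events(path) -> pd.DataFrame:
    table = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    missing = set(EVENT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"event table missing columns: {sorted(missing)}")
    return table


def lowpass_filter(trace: Trace, cutoff_hz: float = 20_000.0, order: int = 4) -> Trace:
    """Optional zero-phase Butterworth low-pass stage applied before detection.

    Mirrors the amplifier-side 20 kHz filter; off by default for synthetic
    traces.  ``cutoff_hz`` must be below the Nyquist frequency.
    """
    from scipy import signal

    nyq = trace.sampling_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    sos = signal.butter(order, cutoff_hz, fs=trace.sampling_rate, output="sos")
    filtered = signal.sosfiltfilt(sos, trace.current)
    return Trace(
        current=filtered,
        sampling_rate=trace.sampling_rate,
        waveform=trace.waveform,
        voltage=trace.voltage,
        start_time=trace.start_time,
    )
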