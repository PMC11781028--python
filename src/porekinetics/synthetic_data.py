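"""Ground-truthed synthetic nanopore digestion experiments.

The generator emulates the statistical structure of the real-time cleavage
assay: a flat, noisy current baseline; Poisson-arriving conductive pulses
confined to the −700 mV capture phases; per-species truncated-normal peak
amplitude and dwell distributions (a 3 kbp reactant around 0.25 nA / 0.20 ms
versus its two 1.5 kbp cleavage products around 0.15 nA / 0.15 ms); and a
species mixture that evolves with digestion time according to a kinetic
model.  Every injected event is recorded in a ground-truth table so that
downstream detection and quantification can be scored exactly.

Two kinetic laws are provided.  A multi-turnover restriction enzyme
(SwaI-like) is modelled as first-order decay of the uncleaved pool with a
rate proportional to the enzyme amount.  A single-turnover RNA-guided
endonuclease (Cas9-RNP-like) adds an initial burst: a fixed fraction of the
substrate is cleaved before the measurement starts (the enzyme stays bound
to its product), and the remainder decays slowly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .trace_io import Trace, WaveformSpec

__all__ = [
    "SpeciesModel",
    "KineticsSpec",
    "SimulationConfig",
    "GroundTruth",
    "REACTANT_3KBP",
    "PRODUCT_1_5KBP",
    "uncleaved_fraction",
    "reactant_share",
    "generate_experiment",
    "write_ground_truth",
    "read_ground_truth",
    "match_events",
    "predicted_probability",
    "implied_initial_slope",
]

KINETIC_MODELS = ("none", "first_order_multi_turnover", "single_turnover_burst")


@dataclass(frozen=True)
class SpeciesModel:
    """Peak-amplitude / dwell distribution of one dsDNA species.

    Amplitudes (nA) and dwells (ms) are drawn from normal distributions
    truncated at zero.  ``capture_weight`` optionally biases the capture
    probability of this species relative to its molar share (default 1:
    capture is molarity-proportional and length-independent).
    """

    name: str
    length_kbp: float
    amp_mean: float  # nA
    amp_sd: float  # nA
    dwell_mean: float  # ms
    dwell_sd: float  # ms
    capture_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.amp_mean <= 0 or self.dwell_mean <= 0:
            raise ValueError("amp_mean and dwell_mean must be positive")
        if self.amp_sd < 0 or self.dwell_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.capture_weight < 0:
            raise ValueError("capture_weight must be non-negative")

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` (amplitude, dwell) pairs, truncated at > 0."""
        amp = _truncated_normal(rng, self.amp_mean, self.amp_sd, n)
        dwell = _truncated_normal(rng, self.dwell_mean, self.dwell_sd, n)
        return amp, dwell


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    if sd == 0:
        return np.full(n, mean)
    a = (0.0 - mean) / sd  # truncate at zero
    return sps.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


#: Uncleaved 3 kbp reactant carrying the central cleavage site.
REACTANT_3KBP = SpeciesModel("3kbp", 3.0, amp_mean=0.25, amp_sd=0.025,
                             dwell_mean=0.20, dwell_sd=0.04)
#: 1.5 kbp cleavage product (two copies per cleaved reactant).
PRODUCT_1_5KBP = SpeciesModel("1.5kbp", 1.5, amp_mean=0.15, amp_sd=0.020,
                              dwell_mean=0.15, dwell_sd=0.03)


@dataclass(frozen=True)
class KineticsSpec:
    """Digestion kinetics governing the time-evolving species mixture.

    ``rate_constant`` is the first-order rate per enzyme unit (min⁻¹ · U⁻¹);
    the effective rate is ``rate_constant * enzyme_units``.  ``start_offset``
    is the mixing-to-measurement delay in minutes (the reaction runs during
    loading, so recording time 0 corresponds to reaction time
    ``start_offset``).  ``burst_fraction`` applies only to the
    single-turnover model: the substrate fraction already cleaved at mixing.
    """

    model: str = "none"
    rate_constant: float = 0.0  # min^-1 per enzyme unit
    enzyme_units: float = 1.0
    burst_fraction: float = 0.0
    start_offset: float = 1.0  # min

    def __post_init__(self) -> None:
        if self.model not in KINETIC_MODELS:
            raise ValueError(f"unknown kinetic model {self.model!r}")
        if self.rate_constant < 0:
            raise ValueError("rate_constant must be non-negative")
        if self.enzyme_units < 0:
            raise ValueError("enzyme_units must be non-negative")
        if not 0.0 <= self.burst_fraction <= 1.0:
            raise ValueError("burst_fraction must lie in [0, 1]")
        if self.start_offset < 0:
            raise ValueError("start_offset must be non-negative")


def uncleaved_fraction(kinetics: KineticsSpec, t) -> Union[float, np.ndarray]:
    """Fraction of the reactant pool still uncleaved at recording time ``t``.

    ``t`` is in minutes since the start of the recording (scalar or array);
    the mixing delay ``start_offset`` is added internally.  The result is
    clipped to [0, 1] and is non-increasing in ``t``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be non-negative")
    if kinetics.model == "none":
        f = np.ones_like(t)
    else:
        keff = kinetics.rate_constant * kinetics.enzyme_units
        decay = np.exp(-keff * (t + kinetics.start_offset))
        if kinetics.model == "first_order_multi_turnover":
            f = decay
        else:  # single_turnover_burst
            f = (1.0 - kinetics.burst_fraction) * decay
    f = np.clip(f, 0.0, 1.0)
    return float(f) if f.ndim == 0 else f


def reactant_share(f, r0: float = 1.0, p0: float = 0.0,
                   w_reactant: float = 1.0, w_product: float = 1.0):
    """Molar share of the reactant among capturable molecules.

    One cleaved parent yields TWO product fragments, so with an initially
    pure reactant pool the share among molecules is ``f / (f + 2(1 − f))``.
    ``r0``/``p0`` are the initial molar fractions of reactant and product,
    ``w_*`` optional per-species capture weights.
    """
    f = np.asarray(f, dtype=float)
    r = w_reactant * r0 * f
    p = w_product * (p0 + 2.0 * r0 * (1.0 - f))
    tot = r + p
    out = np.divide(r, tot, out=np.ones_like(r), where=tot > 0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimulationConfig:
    """Complete description of one synthetic kinetic experiment."""

    sampling_rate: float = 100_000.0  # Hz
    baseline_mean: float = 2.0  # nA (magnitude at the capture voltage)
    baseline_sigma: float = 0.01  # nA
    capture_rate: float = 2.0  # events/s during capture phases
    species: tuple[SpeciesModel, ...] = (REACTANT_3KBP, PRODUCT_1_5KBP)
    fractions: tuple[float, ...] = (1.0, 0.0)  # initial molar fractions
    waveform: WaveformSpec = field(default_factory=WaveformSpec)
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    seed: int = 0
    pulse_shape: str = "gaussian"  # or "rect"
    collision_gap_ms: float = 2.0
    collision_warn_frac: float = 0.2

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.baseline_sigma <= 0:
            raise ValueError("baseline_sigma must be positive")
        if self.capture_rate < 0:
            raise ValueError("capture_rate must be non-negative")
        if len(self.species) != len(self.fractions):
            raise ValueError("species and fractions must have equal length")
        if len(self.species) == 0:
            raise ValueError("at least one species required")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("initial fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("fractions must be non-negative")
        if self.kinetics.model != "none" and len(self.species) != 2:
            raise ValueError(
                "kinetic models require exactly two species (reactant, product)"
            )
        if self.pulse_shape not in ("gaussian", "rect"):
            raise ValueError(f"unknown pulse shape {self.pulse_shape!r}")

    @property
    def duration(self) -> float:
        return self.waveform.total_duration


@dataclass
class GroundTruth:
    """Injected-event records plus the analytic per-minute uncleaved fraction.

    ``events`` columns: ``time_s`` (pulse peak time), ``species``, ``amp_nA``,
    ``dwell_ms``, ``collision`` (True when another event lies within the
    collision gap, so the two pulses are merged in the trace).
    ``fractions`` columns: ``minute`` (1-based), ``f_true`` evaluated at the
    minute midpoint.
    """

    events: pd.DataFrame
    fractions: pd.DataFrame
    seed: int = 0
    collision_warning: bool = False

    @property
    def n_events(self) -> int:
        return len(self.events)


_GT_COLUMNS = ["time_s", "species", "amp_nA", "dwell_ms", "collision"]


def _arrival_times(
    rng: np.random.Generator, wf: WaveformSpec, rate: float
) -> np.ndarray:
    """Poisson arrivals restricted to capture phases, as absolute times (s)."""
    total_capture = wf.n_loops * wf.capture_duration
    n = rng.poisson(rate * total_capture)
    u = rng.uniform(0.0, total_capture, size=n)  # capture-local time
    u.sort()
    loop = np.floor(u / wf.capture_duration)
    within = u - loop * wf.capture_duration
    return loop * wf.period + wf.rest_duration + within


def generate_experiment(config: SimulationConfig) -> tuple[Trace, GroundTruth]:
    """Simulate one kinetic translocation experiment.

    Returns the full current trace (baseline noise plus conductive pulses,
    as positive-going excursions on the baseline magnitude) and the exact
    ground truth.  Identical configs produce bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    wf = config.waveform
    rate = config.sampling_rate
    n_samples = int(round(wf.total_duration * rate))

    times = _arrival_times(rng, wf, config.capture_rate)
    n_events = times.size

    # species assignment from the time-evolving mixture
    if n_events:
        if config.kinetics.model == "none":
            w = np.array([s.capture_weight * f
                          for s, f in zip(config.species, config.fractions)])
            p = w / w.sum()
            species_idx = rng.choice(len(config.species), size=n_events, p=p)
        else:
            f = uncleaved_fraction(config.kinetics, times / 60.0)
            share = reactant_share(
                f,
                r0=config.fractions[0],
                p0=config.fractions[1],
                w_reactant=config.species[0].capture_weight,
                w_product=config.species[1].capture_weight,
            )
            species_idx = (rng.uniform(size=n_events) >= share).astype(int)
    else:
        species_idx = np.empty(0, dtype=int)

    amps = np.empty(n_events)
    dwells = np.empty(n_events)
    for i, sp in enumerate(config.species):
        mask = species_idx == i
        if mask.any():
            amps[mask], dwells[mask] = sp.draw(rng, int(mask.sum()))

    # collision flags: neighbours closer than the collision gap merge in the
    # trace (pulses superpose) but both stay in the ground truth
    collision = np.zeros(n_events, dtype=bool)
    if n_events > 1:
        close = np.diff(times) < config.collision_gap_ms / 1000.0
        collision[:-1] |= close
        collision[1:] |= close
    collision_warning = False
    if n_events and collision.mean() > config.collision_warn_frac:
        collision_warning = True
        warnings.warn(
            f"{collision.mean():.0%} of injected events collide within "
            f"{config.collision_gap_ms} ms; capture_rate may be too high",
            stacklevel=2,
        )

    current = config.baseline_mean + rng.normal(0.0, config.baseline_sigma, n_samples)
    _render_pulses(current, config, times, amps, dwells)

    trace = Trace(current=current, sampling_rate=rate, waveform=wf)

    names = np.array([s.name for s in config.species])
    events = pd.DataFrame(
        {
            "time_s": times,
            "species": names[species_idx] if n_events else np.array([], dtype=object),
            "amp_nA": amps,
            "dwell_ms": dwells,
            "collision": collision,
        }
    )
    minutes = np.arange(1, int(np.ceil(wf.total_duration / 60.0)) + 1)
    f_true = uncleaved_fraction(config.kinetics, minutes - 0.5)
    fractions = pd.DataFrame({"minute": minutes, "f_true": np.atleast_1d(f_true)})
    gt = GroundTruth(events=events, fractions=fractions, seed=config.seed,
                     collision_warning=collision_warning)
    return trace, gt


def _render_pulses(current, config, times, amps, dwells) -> None:
    """Add conductive pulses in place, clipped to their capture phase."""
    rate = config.sampling_rate
    wf = config.waveform
    period = wf.period
    for t, a, d in zip(times, amps, dwells):
        loop = int(t // period)
        cap_lo = int(round((loop * period + wf.rest_duration) * rate))
        cap_hi = int(round((loop * period + period) * rate))
        if config.pulse_shape == "gaussian":
            sigma_t = (d / 1000.0) / 2.354820045  # FWHM -> sd, in s
            half = 4.0 * sigma_t
            i0 = max(cap_lo, int(np.floor((t - half) * rate)))
            i1 = min(cap_hi, int(np.ceil((t + half) * rate)) + 1)
            tt = np.arange(i0, i1) / rate
            current[i0:i1] += a * np.exp(-0.5 * ((tt - t) / sigma_t) ** 2)
        else:  # rectangular, width = dwell
            half = d / 2000.0
            i0 = max(cap_lo, int(np.ceil((t - half) * rate)))
            i1 = min(cap_hi, int(np.floor((t + half) * rate)) + 1)
            current[i0:i1] += a


# ---------------------------------------------------------------------------
# ground-truth I/O
# ---------------------------------------------------------------------------


def write_ground_truth(gt: GroundTruth, path, fractions_path=None) -> Path:
    """Write the injected-event table as TSV (lossless round trip).

    ``fractions_path`` optionally receives the per-minute true uncleaved
    fraction as a second TSV.
    """
    path = Path(path)
    out = gt.events.copy()
    out["collision"] = out["collision"].astype(int)
    out.to_csv(path, sep="\t", index=False, columns=_GT_COLUMNS,
               float_format="%.17g")
    if fractions_path is not None:
        gt.fractions.to_csv(Path(fractions_path), sep="\t", index=False,
                            float_format="%.17g")
    return path


def read_ground_truth(path, fractions_path=None) -> GroundTruth:
    events = pd.read_csv(Path(path), sep="\t", dtype={"species": str},
                         float_precision="round_trip")
    if list(events.columns) != _GT_COLUMNS:
        raise ValueError(f"unexpected ground-truth columns: {list(events.columns)}")
    events["collision"] = events["collision"].astype(bool)
    if len(events) == 0:
        events = events.astype({"time_s": float, "amp_nA": float, "dwell_ms": float})
    if fractions_path is not None:
        fractions = pd.read_csv(Path(fractions_path), sep="\t")
    else:
        fractions = pd.DataFrame({"minute": [], "f_true": []})
    return GroundTruth(events=events, fractions=fractions)


# ---------------------------------------------------------------------------
# scoring detected events against the ground truth
# ---------------------------------------------------------------------------


def match_events(
    true_times: np.ndarray, detected_times: np.ndarray, tol_s: float = 1e-3
) -> tuple[float, float, int]:
    """Greedy one-to-one matching of detected to injected event times.

    Returns ``(recall, precision, n_matched)``.  Both inputs are absolute
    times in seconds; a detection matches an injected event when within
    ``tol_s``.  Restrict ``true_times`` to the analysed windows before
    calling if detection only saw part of the trace.
    """
    true_times = np.sort(np.asarray(true_times, dtype=float))
    detected_times = np.sort(np.asarray(detected_times, dtype=float))
    i = j = matched = 0
    while i < true_times.size and j < detected_times.size:
        dt = detected_times[j] - true_times[i]
        if abs(dt) <= tol_s:
            matched += 1
            i += 1
            j += 1
        elif dt < 0:
            j += 1
        else:
            i += 1
    recall = matched / true_times.size if true_times.size else 1.0
    precision = matched / detected_times.size if detected_times.size else 1.0
    return recall, precision, matched


# ---------------------------------------------------------------------------
# analytic expectations (closed-form, independent of the detection/KDE path)
# ---------------------------------------------------------------------------


def _expected_events_per_minute(config: SimulationConfig,
                                analysis_window_s: float = 5.0) -> float:
    wf = config.waveform
    return config.capture_rate * (analysis_window_s / wf.period) * 60.0


def predicted_probability(
    config: SimulationConfig,
    lower: float,
    upper: float,
    minutes: np.ndarray,
    kde_bandwidth: Optional[float] = None,
) -> np.ndarray:
    """Closed-form expectation of the boundary-bounded detection probability.

    For each recording minute the species mixture is evaluated at the minute
    midpoint, each species' amplitude distribution is convolved with the KDE
    kernel (Scott-rule bandwidth from the expected per-minute event count
    unless ``kde_bandwidth`` is given, in nA), and the Gaussian mass between
    the boundaries is mixed accordingly.  Used as an independent oracle for
    parameter-recovery checks; returns percent.
    """
    minutes = np.asarray(minutes, dtype=float)
    f = np.atleast_1d(uncleaved_fraction(config.kinetics, minutes - 0.5))
    if config.kinetics.model == "none":
        w = np.array([s.capture_weight * fr
                      for s, fr in zip(config.species, config.fractions)])
        shares = np.tile(w / w.sum(), (minutes.size, 1))
    else:
        share_r = reactant_share(
            f, r0=config.fractions[0], p0=config.fractions[1],
            w_reactant=config.species[0].capture_weight,
            w_product=config.species[1].capture_weight,
        )
        shares = np.column_stack([share_r, 1.0 - np.atleast_1d(share_r)])

    mus = np.array([s.amp_mean for s in config.species])
    sds = np.array([s.amp_sd for s in config.species])
    probs = np.empty(minutes.size)
    n_min = _expected_events_per_minute(config)
    for k in range(minutes.size):
        w = shares[k]
        if kde_bandwidth is None:
            mix_mu = float(w @ mus)
            mix_var = float(w @ (sds**2 + mus**2) - mix_mu**2)
            h = n_min ** (-0.2) * np.sqrt(max(mix_var, 1e-12))
        else:
            h = kde_bandwidth
        smooth_sd = np.sqrt(sds**2 + h**2)
        mass = sps.norm.cdf((upper - mus) / smooth_sd) - sps.norm.cdf(
            (lower - mus) / smooth_sd
        )
        probs[k] = 100.0 * float(w @ mass)
    return probs


def implied_initial_slope(
    config: SimulationConfig,
    lower: float,
    upper: float,
    window: tuple[int, int] = (1, 15),
) -> float:
    """OLS slope (%/min) of the predicted probability over the fit window."""
    minutes = np.arange(window[0], window[1] + 1, dtype=float)
    p = predicted_probability(config, lower, upper, minutes)
    res = sps.linregress(minutes, p)
    return float(res.slope)
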