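# Methods

`porekinetics` analyses real-time solid-state nanopore recordings of
endonuclease digestion.  A glass nanopipette filled with a reaction mixture
(a 3 kbp double-stranded DNA substrate carrying a central cleavage site,
plus a restriction enzyme such as SwaI or a Cas9 ribonucleoprotein) is
immersed in a PEG/KCl polymer-electrolyte bath.  Each translocating DNA
molecule produces a *conductive* pulse — a transient increase in
conductance magnitude, opposite in sign to the classic resistive blockade —
whose peak amplitude discriminates the 3 kbp reactant (~0.25–0.3 nA) from
its two 1.5 kbp cleavage products (~0.15 nA).  Watching the amplitude
population shift over tens of minutes yields single-molecule cleavage
kinetics without labels or gels.

## Measurement model and waveform

The applied-voltage program alternates a 3.5 s rest phase (+100 mV, DNA is
pushed away from the pore, preventing clogging) with a 6 s capture phase
(−700 mV, DNA translocates), looped 180–360 times (30–60 min).  One period
(9.5 s) is a *sweep*.  Analysis uses seconds 4–9 of each sweep, counted
from the rest-phase onset — i.e. capture seconds 0.5–5.5, treating the
first half second after the voltage step as settling.  This is the only
self-consistent reading of a 5 s analysis window inside a 6 s capture
phase; a window anchored on the capture onset instead is available via
`window_origin="capture"` but cannot fit the default waveform.  Recording
starts an estimated 1 min after reagent mixing (`start_offset`), so
recording minute *t* corresponds to reaction time *t* + 1 min.

All coordinates are 0-based, half-open sample ranges.  Recordings are
nominally digitized at 100 kHz with an amplifier-side 20 kHz low-pass; an
optional zero-phase Butterworth stage (`lowpass_hz`) mirrors that filter
and is off by default for synthetic traces.

## Synthetic experiments

The generator (`synthetic_data`) emulates the assay's statistical
structure, not its electrochemistry:

* **Baseline** — white Gaussian noise around a constant open-pore level
  (defaults 2.0 ± 0.01 nA).  1/f noise, drift and capacitive transients at
  the voltage steps are not modelled.
* **Events** — Poisson arrivals at `capture_rate` (default 2 s⁻¹),
  restricted to capture phases.  Each event draws a species from the
  current mixture and then a peak amplitude and dwell (FWHM) from that
  species' truncated-normal model.  Defaults: 3 kbp reactant 0.25 ± 0.025
  nA, 0.20 ± 0.04 ms; 1.5 kbp product 0.15 ± 0.020 nA, 0.15 ± 0.03 ms.
  Pulses are Gaussian (FWHM = dwell) added onto the baseline magnitude;
  rectangular pulses are available.  Events closer than 2 ms superpose in
  the trace and are collision-flagged in the ground truth.
* **Kinetics** — the uncleaved fraction f(t) of the reactant pool follows
  one of three laws: `none` (f ≡ 1), `first_order_multi_turnover`
  (f = exp(−k·u·(t + t₀)); k per enzyme unit u, mimicking a multi-turnover
  restriction enzyme whose decay rate scales with enzyme amount), or
  `single_turnover_burst` (a fraction of the substrate is cleaved before
  measurement and the remainder decays slowly — the signature of a
  single-turnover, product-bound endonuclease such as a Cas9 RNP, which
  can cut most of its substrate within seconds of mixing).
* **Stoichiometry** — each cleavage yields two product molecules, so the
  reactant's molar share among capturable molecules is f/(f + 2(1 − f)).
  Capture probability is assumed molarity-proportional and
  length-independent; a per-species `capture_weight` exposes the untested
  alternative that shorter fragments capture at different rates.

Identical configurations reproduce bit-identical traces and ground truth.

## Event detection

Per analysis window, the baseline is estimated robustly (median, σ =
1.4826·MAD — insensitive to events at the observed ≲1% duty cycle) and a
threshold is placed 10σ above it, in the conductive direction.  Each
contiguous supra-threshold excursion, extended to the nearest baseline
crossings, is one event; excursions separated by <0.1 ms are merged (the
split-peak tie-break, well below the 0.15–0.2 ms dwell scale of
interest).  Peak amplitude is the maximum deviation from the baseline;
dwell is the full width at half maximum with sub-sample linear
interpolation (threshold-crossing width via `dwell_mode="threshold"`).
Baselines are per-window because sweep-to-sweep drift is expected in real
recordings; no within-window drift correction is applied.

## Population quantification (KDE → PDF → AUC)

Events are binned by recording minute (1-based, half-open).  Each minute
with ≥10 events yields a Gaussian-kernel KDE of peak amplitudes
(Scott's-rule bandwidth; an absolute bandwidth can be forced), evaluated
on a 512-point grid spanning [0, 1.2 × max amplitude] shared across the
experiment so that fixed boundaries index every minute consistently.
Minutes with fewer events are *unusable* — their probability is missing,
never zero.

The detection probability of the reactant is the trapezoidal area under
the minute's PDF between two boundaries fixed once per experiment at ±10%
of the reactant's peak amplitude in the minute-1 PDF (minute 1 normally
contains both populations).  The reactant peak is the highest-amplitude
local maximum with prominence ≥10% of the density maximum — an
amplitude rule, not a density rule, because the reactant is always the
larger molecule even when the product population dominates.  When an
`expected_region` is supplied the prominence floor is referenced to the
density inside that region; if no qualifying mode exists at all (fully
digested starts), explicit boundaries around the species' known amplitude
(`reference_peak`) are the supported fallback.  Because a PDF integrates
to one, the full-grid AUC is 100% and the starting percentage depends on
the boundary width — series therefore always carry their boundary
metadata.  Dwell times are carried for QC only; classification uses peak
amplitude alone.

## Kinetics and statistics

The reaction-rate statistic is the ordinary-least-squares slope of
probability vs time over the initial-velocity window (minutes 1–15 by
default, inclusive; missing minutes dropped, not interpolated), in
percentage points per minute; the reported *rate* is its negation.  A
zero-variance response has undefined r², reported as 0 with a degenerate
flag.  Mean rates across replicates, with the standard error of the mean,
are related to enzyme amount by a second OLS fit whose R² measures
linearity.  Conditions are classified by slope: inactive (m > −0.1),
active (m < −1), weakly active in between; thresholds are configurable.

Replicate probabilities at two time points (typically minutes 1 and 30)
are compared with the classical equal-variance two-tailed unpaired t-test
(Welch form optional), gated on Levene's homoscedasticity test
(mean-centred; median-centred Brown–Forsythe optional).  Significance
codes: ns (p ≥ 0.05), `*` (<0.05), `**` (<0.005), `****` (<0.0001); no
`***` tier is defined on this scale.  Degenerate inputs are handled
explicitly: identical groups give t = 0, p = 1; location-shifted spread
patterns give W = 0, p = 1.

## Numerical and design choices

* Problem sizes: simulation-heavy tests and `scripts/acceptance.py` run
  the generator at 25 kHz instead of 100 kHz (a 0.15 ms dwell is still
  ~4 samples FWHM, resolved by interpolation) with 16-minute recordings
  for initial-velocity fits and 30-minute recordings for controls.
* The boundary AUC uses linear interpolation of the density at the exact
  boundary positions, so probabilities vary continuously with boundaries
  and widening boundaries never decreases the probability.  It agrees
  with the exact per-sample Gaussian kernel mass to <0.1 pp.
* Trace tables and event/ground-truth TSVs are written with 17
  significant digits and read back with round-trip float parsing, so file
  round trips are bit-exact.
* A closed-form expectation (`predicted_probability`) maps the kinetic
  law, the doubling stoichiometry and the KDE smoothing (Gaussian
  convolution with a Scott-rule bandwidth from the expected per-minute
  event count) to the boundary-bounded probability.  It serves as an
  independent oracle for parameter-recovery checks; recovered
  initial-velocity slopes agree with it to within a few percent on
  average.

## Known limitations

* **Window saturation.** The fixed-window initial-velocity slope is
  proportional to the underlying rate only while k·u·(window) ≲ 1.  With
  the exponential decay law, fast conditions (e.g. k_eff ≳ 0.1 min⁻¹)
  digest most of the substrate inside the 15-min window, and the fitted
  slope saturates and then *decreases* with enzyme amount even though the
  generator's rate constant keeps rising.  This mirrors the fast
  single-turnover regime, where most substrate is already cleaved when
  measurement starts and only the residual slow phase is observable.
  Consequently, linearity of measured rate vs enzyme amount should only
  be expected (and is only claimed) in the sub-saturating regime.
* **Sampling noise of the probability statistic.** At ~2 captures/s and a
  5 s window per 9.5 s sweep, a minute holds ~60 analysable events, giving
  the per-minute probability a binomial-scale standard error of ~6 pp and
  a 30-minute slope fit a standard error of ~0.13 pp/min.  Single-run
  control slopes therefore scatter well beyond ±0.1; flatness bounds are
  evaluated on replicate-mean series (as the rate figures are fitted in
  practice), and stationarity tests assert a flat fitted trend rather
  than a raw range bound.
* The generator does not emulate 1/f noise, capacitive transients,
  pore-geometry or electro-osmotic effects, amplitude drift with baseline
  level, or sub-event structure (folding, knots); passing tests show the
  analysis chain is correct and well calibrated for the modelled
  statistics, not that it is robust to every artefact of real recordings.
* Michaelis–Menten parameterization and full-progress-curve exponential
  fitting are out of scope: the linear initial-velocity statistic is the
  assay's rate definition.
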