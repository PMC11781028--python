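"""KDE/AUC population-quantification tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from porekinetics import (
    Boundaries,
    MinuteBin,
    bin_by_minute,
    build_grid,
    estimate_pdf,
    find_reference_peak,
    probability_between,
    probability_series,
    read_probability_series,
    write_probability_series,
)
from porekinetics.kinetics import fit_line


def events_frame(onsets, amps):
    return pd.DataFrame({"onset_s": np.asarray(onsets, dtype=float),
                         "amp_nA": np.asarray(amps, dtype=float)})


def mixture_events(rng, n_per_min, minutes, w_reactant,
                   reactant=(0.25, 0.025), product=(0.15, 0.02)):
    """Stationary two-population event stream, n events per minute."""
    onsets, amps = [], []
    for m in range(minutes):
        t = rng.uniform(m * 60, (m + 1) * 60, n_per_min)
        is_r = rng.uniform(size=n_per_min) < w_reactant
        a = np.where(
            is_r,
            rng.normal(*reactant, n_per_min),
            rng.normal(*product, n_per_min),
        )
        onsets.append(t)
        amps.append(a)
    return events_frame(np.concatenate(onsets), np.concatenate(amps))


class TestBinByMinute:
    def test_half_open_minute_assignment(self):
        ev = events_frame([10.0, 60.0, 70.0], [0.2, 0.2, 0.2])
        bins = bin_by_minute(ev)
        assert [b.n_events for b in bins] == [1, 2]
        # the event at exactly 60 s lands in minute 2
        assert bins[1].minute == 2

    def test_empty_bins_retained(self):
        ev = events_frame([10.0, 250.0], [0.2, 0.2])
        bins = bin_by_minute(ev, total_duration_s=360.0)
        assert [b.minute for b in bins] == [1, 2, 3, 4, 5, 6]
        assert [b.n_events for b in bins] == [1, 0, 0, 0, 1, 0]

    def test_uniform_arrivals_fill_bins_evenly(self, rng):
        ev = events_frame(rng.uniform(0, 600, 600), np.full(600, 0.2))
        bins = bin_by_minute(ev, 600.0)
        counts = np.array([b.n_events for b in bins])
        assert counts.sum() == 600
        assert np.all(np.abs(counts - 60) < 4 * np.sqrt(60))


class TestEstimatePdf:
    def test_mode_recovers_generating_mean(self, rng):
        amps = rng.normal(0.25, 0.02, 5000)
        grid = build_grid(amps)
        pdf = estimate_pdf(MinuteBin(1, amps), grid)
        assert grid[np.argmax(pdf.density)] == pytest.approx(0.25, abs=0.005)

    def test_normalization(self, rng):
        """Per-minute densities on the shared experiment grid integrate to
        one, from sparse to dense minutes."""
        pool = np.where(
            rng.uniform(size=5000) < 0.6,
            rng.normal(0.25, 0.025, 5000),
            rng.normal(0.15, 0.02, 5000),
        )
        grid = build_grid(pool)  # shared across minutes, as in the pipeline
        for n in (10, 100, 5000):
            pdf = estimate_pdf(MinuteBin(1, pool[:n]), grid)
            assert pdf.integral() == pytest.approx(1.0, abs=1e-3)

    def test_too_few_events_is_unusable_not_zero(self):
        assert estimate_pdf(MinuteBin(1, np.full(5, 0.2)), np.linspace(0, 1, 64)) is None

    def test_fixed_bandwidth_on_repeated_value(self):
        """A degenerate sample with an explicit kernel width is a single
        symmetric kernel centred on the value."""
        amps = np.full(50, 0.2)
        grid = np.linspace(0.0, 0.4, 401)
        pdf = estimate_pdf(MinuteBin(1, amps), grid, bandwidth=0.01)
        peak = grid[np.argmax(pdf.density)]
        assert peak == pytest.approx(0.2, abs=1e-3)
        np.testing.assert_allclose(
            pdf.density, sps.norm.pdf(grid, 0.2, 0.01), rtol=1e-10, atol=1e-10
        )
        # Scott's rule cannot handle the same sample
        with pytest.raises(ValueError, match="bandwidth"):
            estimate_pdf(MinuteBin(1, amps), grid)


class TestReferencePeak:
    def make_pdf(self, rng, w_reactant=0.5, n=4000):
        ev = mixture_events(rng, n, 1, w_reactant)
        amps = ev["amp_nA"].to_numpy()
        return estimate_pdf(MinuteBin(1, amps), build_grid(amps))

    def test_balanced_bimodal_picks_higher_amplitude_mode(self, rng):
        pdf = self.make_pdf(rng, 0.5)
        step = pdf.grid[1] - pdf.grid[0]
        assert find_reference_peak(pdf) == pytest.approx(0.25, abs=5 * step)

    def test_minor_high_mode_still_wins(self, rng):
        """Higher-amplitude rule, not higher-density rule (20:80 mixture)."""
        pdf = self.make_pdf(rng, 0.2)
        assert find_reference_peak(pdf) == pytest.approx(0.25, abs=0.01)
        # the density rule would pick the product mode instead
        assert find_reference_peak(pdf, mode="global_max") == pytest.approx(
            0.15, abs=0.01
        )

    def test_unimodal(self, rng):
        amps = rng.normal(0.30, 0.02, 3000)
        pdf = estimate_pdf(MinuteBin(1, amps), build_grid(amps))
        assert find_reference_peak(pdf) == pytest.approx(0.30, abs=0.005)

    def test_no_peak_in_region_lists_candidates(self, rng):
        amps = rng.normal(0.15, 0.02, 3000)
        pdf = estimate_pdf(MinuteBin(1, amps), build_grid(amps, pad=3.0))
        with pytest.raises(ValueError, match="candidate"):
            find_reference_peak(pdf, expected_region=(0.3, 0.4))


class TestProbabilityBetween:
    def gaussian_pdf(self, rng, n=5000):
        amps = rng.normal(0.25, 0.02, n)
        return estimate_pdf(MinuteBin(1, amps), build_grid(amps)), amps

    def test_full_support_is_100_percent(self, rng):
        pdf, _ = self.gaussian_pdf(rng)
        b = Boundaries(pdf.grid[0], pdf.grid[-1], 0.25)
        assert probability_between(pdf, b) == pytest.approx(100.0, abs=0.1)

    def test_zero_width_is_zero(self, rng):
        pdf, _ = self.gaussian_pdf(rng)
        assert probability_between(pdf, Boundaries(0.25, 0.25, 0.25)) == 0.0

    def test_gaussian_cdf_oracle(self, rng):
        """N(0.25, 0.02) mass between 0.225-0.275 matches 2Φ(1.25)-1,
        slightly widened by the KDE kernel."""
        pdf, _ = self.gaussian_pdf(rng)
        p = probability_between(pdf, Boundaries(0.225, 0.275, 0.25))
        expected = 100 * (2 * sps.norm.cdf(1.25) - 1)  # 78.87
        assert p == pytest.approx(expected, abs=1.0)

    def test_outside_grid_errors(self, rng):
        pdf, _ = self.gaussian_pdf(rng)
        with pytest.raises(ValueError, match="outside"):
            probability_between(pdf, Boundaries(0.0, pdf.grid[-1] + 1.0, 0.25))

    def test_agrees_with_kernel_mass_oracle(self, rng):
        """Trapezoidal boundary AUC equals the exact per-sample Gaussian
        kernel mass to within 0.1 percentage points."""
        pdf, amps = self.gaussian_pdf(rng)
        h = pdf.bandwidth
        lo_g, hi_g = pdf.grid[0], pdf.grid[-1]
        for _ in range(100):
            lo, hi = np.sort(rng.uniform(lo_g, hi_g, 2))
            direct = 100 * np.mean(
                sps.norm.cdf((hi - amps) / h) - sps.norm.cdf((lo - amps) / h)
            )
            trap = probability_between(pdf, Boundaries(lo, hi, 0.25))
            assert abs(trap - direct) <= 0.1

    @settings(derandomize=True, max_examples=40)
    @given(data=st.data())
    def test_widening_boundaries_never_decreases_probability(self, data):
        pdf, _ = self.gaussian_pdf(np.random.default_rng(7))
        top = pdf.grid[-1]
        lo = data.draw(st.floats(0.01, 0.24))
        hi = data.draw(st.floats(0.26, 0.9 * top))
        pad_lo = data.draw(st.floats(0.0, 0.01))
        pad_hi = data.draw(st.floats(0.0, min(0.01, top - hi)))
        inner = probability_between(pdf, Boundaries(lo, hi, 0.25))
        outer = probability_between(
            pdf, Boundaries(max(lo - pad_lo, 0.0), hi + pad_hi, 0.25)
        )
        assert outer >= inner - 1e-9


class TestProbabilitySeries:
    def test_stationary_mixture_is_flat(self, rng):
        """With no digestion the fitted trend of the series is flat."""
        ev = mixture_events(rng, 500, 30, 0.6)
        series = probability_series(ev, total_duration_s=1800.0)
        assert np.all(series.usable())
        fit = fit_line(series.minutes, series.probability)
        assert abs(fit.slope) < 0.05

    def test_all_product_stays_below_15_percent(self, rng):
        """Boundaries at the reactant peak see only the product tail."""
        ev = mixture_events(rng, 200, 10, 0.0)
        series = probability_series(
            ev, total_duration_s=600.0,
            boundaries=Boundaries.from_reference(0.25),
        )
        assert np.nanmax(series.probability) <= 15.0

    def test_digestion_series_decreases(self, digestion_result):
        series = digestion_result.series
        ok = series.usable()
        rho = sps.spearmanr(series.minutes[ok], series.probability[ok]).statistic
        assert rho < -0.9

    def test_amplitude_rescaling_equivariance(self, rng):
        """Rescaling all amplitudes by c rescales the reference peak by c
        and leaves every probability unchanged."""
        ev = mixture_events(rng, 300, 5, 0.6)
        s1 = probability_series(ev, total_duration_s=300.0)
        ev2 = ev.copy()
        ev2["amp_nA"] *= 3.0
        s2 = probability_series(ev2, total_duration_s=300.0)
        assert s2.boundaries.reference_peak == pytest.approx(
            3.0 * s1.boundaries.reference_peak, rel=1e-9
        )
        np.testing.assert_allclose(s2.probability, s1.probability, atol=1e-8)

    def test_unusable_source_minute_suggests_alternative(self, rng):
        ev = mixture_events(rng, 100, 3, 0.6)
        sparse = pd.concat(
            [ev[ev.onset_s >= 60], events_frame([5.0], [0.25])]
        )
        with pytest.raises(ValueError, match="usable minute is 2"):
            probability_series(sparse, total_duration_s=180.0)

    def test_sparse_minutes_are_nan(self, rng):
        ev = mixture_events(rng, 100, 2, 0.6)
        ev = ev[(ev.onset_s < 60) | (ev.onset_s >= 110)]  # thin minute 2
        ev2 = pd.concat([ev, events_frame([200.0] * 3, [0.25] * 3)])
        series = probability_series(ev2, total_duration_s=240.0)
        assert series.usable()[0]
        assert not series.usable()[3]  # 3 events < min_events

    def test_roundtrip(self, tmp_path, rng):
        ev = mixture_events(rng, 100, 4, 0.6)
        series = probability_series(ev, total_duration_s=240.0)
        p = write_probability_series(series, tmp_path / "prob.tsv")
        back = read_probability_series(p)
        np.testing.assert_allclose(back.probability, series.probability)
        assert back.boundaries.lower == pytest.approx(series.boundaries.lower)
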