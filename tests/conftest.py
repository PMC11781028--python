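"""Shared fixtures: small synthetic experiments reused across test modules.

Simulations run at a reduced 25 kHz sampling rate (pulse FWHM is still 4–5
samples, resolved by interpolated width measurement) so the whole suite
stays fast; the package default remains the instrument's 100 kHz.
"""

import numpy as np
import pytest

from porekinetics import (
    AnalysisSettings,
    KineticsSpec,
    SimulationConfig,
    WaveformSpec,
    generate_experiment,
    run_experiment,
)

SIM_RATE = 25_000.0  # Hz, reduced problem size for tests


def digestion_config(seed=1, units=5.0, n_loops=102, rate_constant=0.02,
                     sampling_rate=SIM_RATE, **kwargs) -> SimulationConfig:
    """A 16-minute SwaI-like digestion with the default species models."""
    return SimulationConfig(
        sampling_rate=sampling_rate,
        seed=seed,
        waveform=WaveformSpec(n_loops=n_loops),
        kinetics=KineticsSpec(
            model="first_order_multi_turnover",
            rate_constant=rate_constant,
            enzyme_units=units,
        ),
        **kwargs,
    )


def stationary_config(seed=1, fractions=(1.0, 0.0), n_loops=40, **kwargs):
    """A no-digestion recording with a fixed species mixture."""
    return SimulationConfig(
        sampling_rate=SIM_RATE,
        seed=seed,
        waveform=WaveformSpec(n_loops=n_loops),
        fractions=fractions,
        **kwargs,
    )


@pytest.fixture(scope="session")
def digestion_experiment():
    """One seeded digestion trace + ground truth (16 min, 5 U)."""
    return generate_experiment(digestion_config())


@pytest.fixture(scope="session")
def digestion_result():
    """The same digestion pushed through the full analysis pipeline."""
    return run_experiment(
        digestion_config(), AnalysisSettings(expected_region=(0.20, 0.35))
    )


@pytest.fixture(scope="session")
def stationary_experiment():
    """A short pure-reactant recording (no digestion), with ground truth."""
    return generate_experiment(stationary_config(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
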