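"""Shared fixtures: small, fast synthetic acquisitions.

Simulated runs use a compressed 10-minute active gradient and a few
hundred precursors so the whole suite stays fast; the generative model
is identical to the full-scale defaults.
"""

from __future__ import annotations

import pytest

from diaqc import dutycycle, simulate, windows
from diaqc.simulate import ChannelSpec, GradientProfile, SimConfig

RANGE = (380.0, 1400.0)

#: compressed gradient: 8-32 %B ramp over minutes 1-11
FAST_GRADIENT = GradientProfile(
    breakpoints=((0.0, 4.0), (1.0, 8.0), (11.0, 32.0), (12.0, 95.0))
)


def make_cycle(n_ms1: int = 1, n_windows: int = 8, max_it: float = 251.0,
               scheme=None) -> dutycycle.DutyCycleSpec:
    if scheme is None:
        scheme = windows.equal_mz_windows(RANGE, n_windows)
    return dutycycle.DutyCycleSpec(
        n_ms1=n_ms1, scheme=scheme, resolving_power=70000,
        max_injection_ms=max_it,
    )


def make_config(seed: int, n_precursors: int = 500, **overrides) -> SimConfig:
    kwargs = dict(
        seed=seed,
        n_precursors=n_precursors,
        gradient=FAST_GRADIENT,
        active_gradient_min=10.0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@pytest.fixture(scope="session")
def sim_result():
    """One standard 3-plex run: 500 precursors, 1 MS1 + 8 MS2 cycle."""
    return simulate.simulate_run(make_config(seed=13), make_cycle())


@pytest.fixture(scope="session")
def sim_two_survey():
    """The same population acquired with two evenly spaced survey scans."""
    return simulate.simulate_run(make_config(seed=13), make_cycle(n_ms1=2))


@pytest.fixture(scope="session")
def sim_dense():
    """Complex-sample run (1000 precursors) for window-placement tests."""
    return simulate.simulate_run(
        make_config(seed=11, n_precursors=1000), make_cycle()
    )


@pytest.fixture(scope="session")
def sim_channel_factors():
    """Run with configured per-channel abundance factors 1 / 2 / 0.5."""
    cfg = make_config(
        seed=17,
        channels=(
            ChannelSpec("d0"),
            ChannelSpec("d4", abundance_factor=2.0),
            ChannelSpec("d8", abundance_factor=0.5),
        ),
    )
    return simulate.simulate_run(cfg, make_cycle())
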