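"""Shared fixtures: single-voxel simulations, phantom, and small noisy studies."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from rsdpet import (
    CompetitionModelParams,
    FrameSchedule,
    InputFunction,
    PhantomSpec,
    ReleaseProfile,
    simulate_reference_tac,
    simulate_study,
    simulate_tac,
)
from rsdpet.simulator import build_phantom

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.uniform(75, 1.0)


@pytest.fixture(scope="session")
def params():
    return CompetitionModelParams()


@pytest.fixture(scope="session")
def input_fn():
    return InputFunction()


@pytest.fixture(scope="session")
def sim_tacs(schedule, params, input_fn):
    """Noise-free single-voxel TACs: reference, baseline, and 100/400 nM release."""
    ref = simulate_reference_tac(params, input_fn, schedule)
    rel400, base = simulate_tac(params, input_fn, ReleaseProfile(DA_peak=400.0), schedule)
    rel100, _ = simulate_tac(params, input_fn, ReleaseProfile(DA_peak=100.0), schedule)
    return {"ref": ref, "baseline": base, "rel100": rel100, "rel400": rel400}


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def analytic_ref(schedule):
    """Analytic reference-like curve for fast fitting oracles."""
    t = schedule.mid_times
    return 8.0 * (np.exp(-0.08 * t) - np.exp(-1.2 * t))


@pytest.fixture(scope="session")
def localized_study_100():
    """One noisy localized-release study at 100 nM (default conditions)."""
    return simulate_study(PhantomSpec(), "localized", 100.0, 1, seed=900)[0]


@pytest.fixture(scope="session")
def null_study():
    """One noisy release-free study (DA_peak = 0)."""
    return simulate_study(PhantomSpec(), "localized", 0.0, 1, seed=901)[0]
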