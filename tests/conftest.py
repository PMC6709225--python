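"""Shared fixtures: deterministic patterns, circuits and one reference
simulation reused across test modules (simulations are the expensive part)."""

import numpy as np
import pytest

import leechheart as lh

#: weights with the structure seen in animals: HE(12) dominated by the
#: rear premotor inputs, HE(8) more evenly innervated
PHYS_WEIGHTS = {
    ("HN3", "HE8"): 0.5, ("HN4", "HE8"): 1.0,
    ("HN6", "HE8"): 0.9, ("HN7", "HE8"): 0.4,
    ("HN3", "HE12"): 0.2, ("HN4", "HE12"): 0.3,
    ("HN6", "HE12"): 1.0, ("HN7", "HE12"): 0.9,
}


@pytest.fixture(scope="session")
def phys_profile():
    return lh.SynapticProfile(
        dict(PHYS_WEIGHTS),
        {k: 0.15 for k in PHYS_WEIGHTS},
        sigma={"HE8": 0.8, "HE12": 0.8},
    )


@pytest.fixture(scope="session")
def clean_pattern():
    """Deterministic pattern: no jitter, no rate variability."""
    return lh.generate_premotor_pattern(
        lh.PatternSpec(n_cycles=7, jitter_sd=0.0, rate_cv=0.0, rate_spread=0.0)
    )


@pytest.fixture(scope="session")
def reference_circuit():
    circuit = lh.apply_parameter_set(
        lh.build_ensemble(), lh.ConductanceParameterSet.reference()
    )
    return lh.set_synaptic_strengths(circuit, lh.SynapticProfile.uniform())


@pytest.fixture(scope="session")
def reference_sim(reference_circuit, clean_pattern):
    """One bilateral ensemble simulation shared by metric-level tests."""
    return lh.simulate(reference_circuit, clean_pattern, duration=36.0, step=2e-4)


@pytest.fixture(scope="session")
def fast_pattern():
    """Short-period pattern for search-level tests (smaller simulations)."""
    return lh.generate_premotor_pattern(
        lh.PatternSpec(period=4.0, n_cycles=6, jitter_sd=0.0, rate_cv=0.0,
                       rate_spread=0.0)
    )


@pytest.fixture(scope="session")
def self_target(fast_pattern, phys_profile):
    """Self-target animal profile: targets measured from the reference
    parameter set itself, so the generating model has MAE = 0."""
    return lh.generate_target_profile(
        lh.ConductanceParameterSet.reference(),
        phys_profile,
        fast_pattern,
        duration=22.0,
        step=2e-4,
        label="self",
    )
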