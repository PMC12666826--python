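import dataclasses

import numpy as np
import pytest

from aclrqc import (
    JointModel,
    default_population,
    extract_metrics,
    segment_phases,
    simulate_trace,
)


@pytest.fixture(scope="session")
def noiseless_aclr():
    """One noiseless successful-rupture simulation (failure at 1.1 mm)."""
    model = JointModel(failure_displacement=1.1, load_noise_sd=0.0)
    return simulate_trace(model, seed=1)


@pytest.fixture(scope="session")
def noiseless_metrics(noiseless_aclr):
    seg = segment_phases(noiseless_aclr.trace)
    return extract_metrics(noiseless_aclr.trace, seg)


@pytest.fixture(scope="session")
def successful_population():
    """Mixed population restricted to the successful-rupture mode."""
    pop = default_population("mixed")
    return dataclasses.replace(
        pop,
        mode_priors={"aclr": 1.0, "no_rupture": 0.0, "fracture": 0.0, "physis": 0.0},
    )


@pytest.fixture(scope="session")
def four_class_population():
    """Mixed population with inflated failure-mode priors for classifier tests."""
    pop = default_population("mixed")
    return dataclasses.replace(
        pop,
        mode_priors={
            "aclr": 0.85,
            "no_rupture": 0.05,
            "fracture": 0.05,
            "physis": 0.05,
        },
    )


def analyze(result):
    """Segment + extract metrics for one simulation result."""
    seg = segment_phases(result.trace)
    return extract_metrics(result.trace, seg)
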