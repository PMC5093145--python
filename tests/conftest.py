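import dataclasses

import numpy as np
import pytest

from snn_spikesort.config import RunConfig
from snn_spikesort.pipeline import evaluate_run, sort_trace
from snn_spikesort.synth import generate, staged_two_unit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def small_sorted_run():
    """A short (13.6 s) staged two-unit recording sorted with defaults.

    Session-scoped: several invariant tests inspect the same run.
    """
    cfg = dataclasses.replace(
        RunConfig(),
        network=dataclasses.replace(RunConfig().network, seed=3),
    )
    trace, truth = generate(staged_two_unit(scale=0.02, seed=3))
    run = sort_trace(trace, cfg)
    return cfg, trace, truth, run


@pytest.fixture(scope="session")
def staged_run_seed1():
    """The full desk-scale (68.1 s) staged protocol at the fixed seed.

    This is the run the acceptance-style selectivity checks score; scoped
    to the session so it is simulated once.
    """
    cfg = dataclasses.replace(
        RunConfig(),
        network=dataclasses.replace(RunConfig().network, seed=1),
    )
    trace, truth = generate(staged_two_unit(scale=0.1, seed=1))
    run = sort_trace(trace, cfg)
    summary = evaluate_run(run, truth, cfg, trace)
    return cfg, trace, truth, run, summary
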