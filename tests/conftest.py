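"""Shared fixtures: each simulated dataset is built once per session."""

from __future__ import annotations

import pytest

from dmrecon.pipeline import reconstruct
from dmrecon.sim import make_fixture

SEED = 1


def _run(fx, sample="tumor"):
    s = fx.samples[sample]
    return reconstruct(s.tumor, s.normal, fx.candidate_segments, fx.reference, fx.params)


@pytest.fixture(scope="session")
def tiny():
    fx = make_fixture("tiny", seed=SEED)
    return fx, _run(fx)


@pytest.fixture(scope="session")
def bridging():
    fx = make_fixture("bridging", seed=SEED)
    return fx, _run(fx)


@pytest.fixture(scope="session")
def relapse_like():
    fx = make_fixture("relapse_like", seed=SEED)
    return fx, _run(fx)


@pytest.fixture(scope="session")
def invalid_cycle():
    fx = make_fixture("invalid_cycle", seed=SEED)
    return fx, _run(fx)


@pytest.fixture(scope="session")
def two_timepoint():
    fx = make_fixture("two_timepoint", seed=SEED)
    return (
        fx,
        _run(fx, "diagnosis"),
        _run(fx, "relapse"),
    )
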