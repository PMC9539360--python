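import numpy as np
import pytest

from ivtbo.anchors import REFERENCE_REACTIONS
from ivtbo.simulator import SimParams, Simulator, load_default_params
from ivtbo.space import ParamSpace, ParamSpec, ReactionConditions, build_default_space


@pytest.fixture(scope="session")
def space():
    return build_default_space()


@pytest.fixture(scope="session")
def sim_params() -> SimParams:
    return load_default_params()


@pytest.fixture(scope="session")
def anchors():
    return REFERENCE_REACTIONS


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def two_real_space() -> ParamSpace:
    """Tiny all-real space for analytic explanation/GP tests."""
    return ParamSpace(
        (
            ParamSpec("a", "real", (0.0, 1.0), ""),
            ParamSpec("b", "real", (0.0, 1.0), ""),
        )
    )


def random_conditions(space: ParamSpace, n: int, seed: int) -> list[ReactionConditions]:
    """Uniform random valid conditions, for round-trip/property tests."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        vals = {}
        for spec in space.specs:
            if spec.kind == "categorical":
                vals[spec.name] = spec.domain[rng.integers(0, len(spec.domain))]
            elif spec.kind == "integer":
                vals[spec.name] = int(rng.integers(spec.lo, spec.hi + 1))
            else:
                vals[spec.name] = float(rng.uniform(spec.lo, spec.hi))
        out.append(ReactionConditions(vals))
    return out


@pytest.fixture(scope="session")
def simulated_log():
    """A reproducible 60-run closed-loop campaign on the bundled simulator."""
    from ivtbo.optimizer import run_closed_loop

    sim = Simulator(seed=7)
    log = run_closed_loop(
        sim.measure_fn(), budget=60, batch_size=4, n_init=16, seed=7
    )
    return log
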