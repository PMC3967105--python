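import pytest

import fastpros as fp

# ---------------------------------------------------------------------------
# Shared fixtures.  Toy models are cheap to build, so model-returning
# fixtures are function-scoped (tests mutate bounds through cobra
# contexts, but a fresh model keeps them fully independent).  The
# randomized toy collections are session-scoped because generation
# includes oracle certification solves.
# ---------------------------------------------------------------------------


@pytest.fixture
def toy1():
    model = fp.make_toy1()
    fp.apply_environment(model, fp.toy_environment())
    return model


@pytest.fixture
def toy_env():
    return fp.toy_environment()


def make_certified_toys(seeds, n_branches_of=lambda s: 2 + s % 3):
    """Generate certified random toys with their environments applied."""
    env = fp.toy_environment()
    models = []
    for seed in seeds:
        model = fp.make_random_toy(
            fp.ToyModelSpec(seed=seed, n_branches=n_branches_of(seed))
        )
        fp.apply_environment(model, env)
        models.append(model)
    return env, models


@pytest.fixture(scope="session")
def random_toys_20():
    """20 certified random toys used by the screening/OptKnock oracles."""
    return make_certified_toys(range(20))


@pytest.fixture(scope="session")
def random_toys_50():
    """50 certified random toys used by the dual-vs-slope comparison."""
    return make_certified_toys(range(100, 150))
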