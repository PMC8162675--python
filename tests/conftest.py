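import numpy as np
import pytest

import thalaswitch as ts


@pytest.fixture(scope="session")
def model1():
    return ts.load_builtin("1")


@pytest.fixture(scope="session")
def model5():
    return ts.load_builtin("5")


@pytest.fixture(scope="session")
def model6():
    return ts.load_builtin("6")


@pytest.fixture(scope="session")
def model5p():
    return ts.load_builtin("5p")


@pytest.fixture(scope="session")
def model6p():
    return ts.load_builtin("6p")


@pytest.fixture(scope="session")
def all_models(model1, model5, model5p, model6, model6p):
    return {"1": model1, "5": model5, "5p": model5p, "6": model6, "6p": model6p}


@pytest.fixture(scope="session")
def slow_cat_models(all_models):
    return {k: m for k, m in all_models.items() if m.has_slow_cat_activation()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
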