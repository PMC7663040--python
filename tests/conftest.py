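import warnings

import pytest

from rpetsafe import ScenarioConfig, get_model, load_tables


@pytest.fixture(scope="session")
def survey():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return load_tables()


@pytest.fixture(scope="session")
def cfg():
    return ScenarioConfig()


@pytest.fixture(scope="session")
def piringer():
    return get_model("piringer")


@pytest.fixture(scope="session")
def welle():
    return get_model("welle")
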