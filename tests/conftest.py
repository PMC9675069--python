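import pytest

from mixoevolve import ModelParams


@pytest.fixture(scope="session")
def specialist() -> ModelParams:
    return ModelParams(z=-1.0)


@pytest.fixture(scope="session")
def linear() -> ModelParams:
    return ModelParams(z=0.0)


@pytest.fixture(scope="session")
def generalist() -> ModelParams:
    return ModelParams(z=1.0)


@pytest.fixture(scope="session", params=[-1.0, 0.0, 1.0],
                ids=["specialist", "linear", "generalist"])
def any_tradeoff(request) -> ModelParams:
    return ModelParams(z=request.param)
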