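import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def wheat_props():
    from wheatdem import datasets

    return datasets.wheat_elastic()


@pytest.fixture(scope="session")
def roller_props():
    from wheatdem import datasets

    return datasets.roller_elastic()


@pytest.fixture(scope="session")
def material():
    from wheatdem import datasets

    return datasets.default_material()


@pytest.fixture(scope="session")
def bbd_runs():
    """The reference Box-Behnken run table as BBRun objects."""
    from wheatdem import datasets
    from wheatdem.repose_rsm import BBRun

    return [BBRun(*r) for r in datasets.BBD_RUNS]
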