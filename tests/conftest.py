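import pytest
from hypothesis import HealthCheck, settings

from gvburden import small_fixture

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Toy synthetic study written once per session; (directory, bundle)."""
    outdir = tmp_path_factory.mktemp("fixture")
    bundle = small_fixture(outdir)
    return outdir, bundle
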