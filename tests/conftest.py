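import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20150)


@pytest.fixture
def tiny_annotations():
    """A 15-gene target and 100-gene reference on one chromosome each."""
    from wgdsig.io import GenomeAnnotation

    target = GenomeAnnotation.from_records(
        "tgt", [(f"t{i}", "c1", i * 100, i * 100 + 50, "+") for i in range(1, 16)]
    )
    reference = GenomeAnnotation.from_records(
        "ref", [(f"r{i}", "d1", i * 100, i * 100 + 50, "+") for i in range(1, 101)]
    )
    return target, reference
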