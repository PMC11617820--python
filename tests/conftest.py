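import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "agderm",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("agderm")


@pytest.fixture()
def face_mask_fresh():
    from agderm.scenarios import face_mask_scenario

    return face_mask_scenario("AgCur", "fresh", wear_hours=8.0)
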