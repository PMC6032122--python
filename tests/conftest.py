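import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session_trace():
    """A 120-s default-condition trace with its ground-truth events."""
    from fixsens.synth import SynthConfig, generate_trace

    cfg = SynthConfig(session_duration=120.0, seed=1)
    trace, events = generate_trace(cfg)
    return cfg, trace, events


@pytest.fixture(scope="session")
def detected_events(default_session_trace):
    from fixsens.msdetect import detect_microsaccades

    _, trace, _ = default_session_trace
    return detect_microsaccades(trace)
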