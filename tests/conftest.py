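"""Shared test configuration."""

from hypothesis import HealthCheck, settings

# deterministic property-test execution in every environment
settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")
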