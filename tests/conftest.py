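import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def vesicle_dataset():
    """One noise-free 30-vesicle image at generator defaults, shared by the
    recovery tests (rendering is the slow part)."""
    from sstembatch.synthetic import generate_vesicle_image, vesicle_grid_spec

    spec = vesicle_grid_spec(30, seed=7)
    image, annotations, truth = generate_vesicle_image(spec)
    return spec, image, annotations, truth
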