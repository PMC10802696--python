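import numpy as np
import pytest

from alignedstrain.phantom import PhantomSpec, render_phantom


def small_spec(**overrides) -> PhantomSpec:
    """Quick desk-scale phantom: 20 frames, 4 slices, 32x32 at 2 mm."""
    kwargs = dict(
        n_frames=20,
        n_slices=4,
        in_plane_size=32,
        spacing=(8.0, 2.0, 2.0),
        endo_radius=10.0,
        epi_radius=16.0,
        rv_thickness=5.0,
        noise_sd=0.0,
        seed=0,
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


@pytest.fixture(scope="session")
def quiet_spec() -> PhantomSpec:
    return small_spec()


@pytest.fixture(scope="session")
def quiet_phantom(quiet_spec):
    return render_phantom(quiet_spec)


@pytest.fixture(scope="session")
def desk_spec() -> PhantomSpec:
    """The default full-size phantom used for registration experiments."""
    return PhantomSpec(noise_sd=2.0, seed=1)


@pytest.fixture(scope="session")
def desk_phantom(desk_spec):
    return render_phantom(desk_spec)
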