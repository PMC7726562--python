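import pytest

from athero3d.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """One default-size phantom with plaques, reused across read-only tests."""
    spec = PhantomSpec(seed=1)
    af, cd, truth = generate_phantom(spec)
    return spec, af, cd, truth


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free phantom: binarization and ground-truth masks are exact."""
    spec = PhantomSpec(seed=2, noise_sd=0.0)
    af, cd, truth = generate_phantom(spec)
    return spec, af, cd, truth


@pytest.fixture(scope="session")
def trained_plaque_model():
    """Desk-scale 2D plaque model shared by the heavy segmentation tests."""
    from athero3d.experiments import train_plaque_desk

    return train_plaque_desk(seed=0)


@pytest.fixture(scope="session")
def anatomy_cv_results():
    """Leave-two-out 3D anatomy cross-validation, shared by heavy tests."""
    from athero3d.experiments import anatomy_cv_experiment

    return anatomy_cv_experiment(seed=0)


@pytest.fixture(scope="session")
def registration_recovery_results():
    """Known-transform atlas registration recovery, shared by heavy tests."""
    from athero3d.experiments import registration_recovery_experiment

    return registration_recovery_experiment(seed=0)
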