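import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def census_phantom():
    """400-spine EM phantom at zero noise with half the spines carrying an SA."""
    from spinetools import simulate

    spec = simulate.VolumePhantomSpec(
        shape=simulate.plan_phantom_shape(400),
        n_spines=400,
        frac_sa=0.5,
        noise_sigma=0.0,
        seed=20220,
    )
    vol, masks, spines = simulate.generate_em_phantom(spec)
    return spec, vol, masks, spines


@pytest.fixture(scope="session")
def census_annotations(census_phantom):
    """Recovered SA annotations for every spine of the census phantom."""
    from spinetools import morphometry

    spec, _vol, masks, spines = census_phantom
    annotations = morphometry.annotate_spines(
        masks, [(s.spine_id, s.bbox) for s in spines], spec.voxel_size_nm
    )
    return spines, annotations
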