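import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture()
def key():
    from morbidgenome import VariantKey

    return VariantKey("1", 12345, "A", "G")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small planted fixture bundle shared across tests (read-only)."""
    from morbidgenome.simulate import PLANTED_CLASSES, generate_fixture_bundle

    out = tmp_path_factory.mktemp("bundle")
    return generate_fixture_bundle(out, {c: 5 for c in PLANTED_CLASSES}, seed=11)


@pytest.fixture(scope="session")
def small_bundle_data(small_bundle):
    return load_bundle(small_bundle)


def load_bundle(bundle):
    """Parse every table of a fixture bundle into in-memory objects."""
    import morbidgenome as mg

    assertions = mg.read_morbid_table(bundle.morbid_hgmd, "hgmd") + mg.read_morbid_table(
        bundle.morbid_clinvar, "clinvar"
    )
    fragments = []
    for role, path in (
        ("1000g", bundle.public_1000g),
        ("exac", bundle.public_exac),
        ("kaviar", bundle.public_kaviar),
    ):
        fragments.extend(mg.read_frequency_table(path, role))
    return {
        "assertions": assertions,
        "fragments": fragments,
        "cohort": mg.read_cohort_table(bundle.cohort),
        "annotations": mg.read_annotation_table(bundle.annotations),
        "quality": mg.read_quality_table(bundle.quality),
    }
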