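import pytest

from plastotype.simulate import (
    PLASTOME_TYPES,
    SyntheticSpec,
    apply_type_transform,
    build_template,
)


@pytest.fixture(scope="session")
def template():
    """A default-scale Type-I genome with ground truth."""
    return build_template(SyntheticSpec(seed=101))


@pytest.fixture(scope="session")
def typed_genomes():
    """One genome per structural type, all derived from one template."""
    rec, truth = build_template(SyntheticSpec(seed=202))
    return {t: apply_type_transform(rec, truth, t) for t in PLASTOME_TYPES}
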