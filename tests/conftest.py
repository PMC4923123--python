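import numpy as np
import pytest

from agefit.atlas import load_atlas
from agefit.config import load_ecrf_model
from agefit.simulate import SyntheticSpec, generate_cohort, generate_volumes
from agefit.stratify import stratify
from agefit.volumes import adjust_volume, analysis_volumes, combine_hemispheres


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def ecrf_model():
    return load_ecrf_model()


@pytest.fixture(scope="session")
def default_spec():
    return SyntheticSpec(n=54, seed=0)


@pytest.fixture(scope="session")
def cohort54(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def design54(cohort54):
    return stratify(cohort54)


@pytest.fixture(scope="session")
def volumes54(cohort54, default_spec, atlas):
    native, truth = generate_volumes(cohort54, default_spec, atlas)
    return native, truth


@pytest.fixture(scope="session")
def adjusted54(volumes54, atlas):
    native, _ = volumes54
    return adjust_volume(combine_hemispheres(native, atlas))


@pytest.fixture(scope="session")
def analysis54(adjusted54):
    return analysis_volumes(adjusted54)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
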