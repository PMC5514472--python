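import numpy as np
import pytest
from hypothesis import settings

# keep example databases out of the repository; tests are derandomised
settings.register_profile("no_db", database=None)
settings.load_profile("no_db")

from tandemhmm.hmm_engine import build_model
from tandemhmm.repeat_spec import ErrorProfile, RepeatSpec
from tandemhmm.simulator import synthetic_locus


@pytest.fixture(scope="session")
def cag_spec() -> RepeatSpec:
    return RepeatSpec("ATXN3", "chr14", 100, 141, "CAG")


@pytest.fixture(scope="session")
def default_profile() -> ErrorProfile:
    return ErrorProfile()


@pytest.fixture(scope="session")
def cag_model(cag_spec, default_profile):
    return build_model(cag_spec, default_profile)


@pytest.fixture(scope="session")
def locus():
    return synthetic_locus()


@pytest.fixture(scope="session")
def errorfree_profile() -> ErrorProfile:
    return ErrorProfile(ins_rate=0.0, del_rate=0.0, sub_rate=0.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
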