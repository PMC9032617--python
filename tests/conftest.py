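import logging

import pytest

from oilnmr.config import RunConfig
from oilnmr.pipeline import run_full_study
from oilnmr.relaxometry import features_table
from oilnmr.synthetic_oils import default_oil_library, generate_study_dataset

logging.getLogger("oilnmr").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def oil_library():
    return default_oil_library()


@pytest.fixture(scope="session")
def study_decays():
    """The default 215-sample adulteration study at the package default seed."""
    return generate_study_dataset(seed=0)


@pytest.fixture(scope="session")
def study_features(study_decays):
    """17-parameter feature table of the default study (shared: extraction is
    the expensive step)."""
    return features_table(study_decays)


@pytest.fixture(scope="session")
def study_report(tmp_path_factory):
    """Full pipeline output at the default seed, shared by the end-to-end and
    acceptance tests."""
    outdir = tmp_path_factory.mktemp("study")
    return run_full_study(RunConfig(seed=0), outdir=outdir)
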