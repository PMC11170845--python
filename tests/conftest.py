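import sys
import warnings
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from mgpk import foce_fit, generate_study, reference_model_spec

warnings.filterwarnings("ignore", message="negative shrinkage")


@pytest.fixture(scope="session")
def study1():
    """One default synthetic study (51 subjects) plus its generating truth."""
    dataset, truth = generate_study(seed=1)
    return dataset, truth


@pytest.fixture(scope="session")
def final_fit1(study1):
    """Final covariate model fitted to the seed-1 study (shared: fits are
    the expensive resource in this suite)."""
    dataset, _ = study1
    return foce_fit(dataset, reference_model_spec())


@pytest.fixture(scope="session")
def small_study():
    """A 12-subject study for fast fit-dependent tests."""
    from mgpk.synthetic_data import StudyDesign

    dataset, truth = generate_study(seed=7, design=StudyDesign(n_subjects=12))
    return dataset, truth
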