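import numpy as np
import pytest

from nervedki.gradients import make_gradient_scheme
from nervedki.synthetic import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def study_scheme():
    """The acquisition used throughout: b = 2000/4000 s/mm^2, 20 directions,
    one b=0 (41 acquisitions)."""
    return make_gradient_scheme(20, [2000.0, 4000.0], n_b0=1, seed=7)


@pytest.fixture(scope="session")
def default_study():
    """One seeded default cohort study shared across tests."""
    return simulate_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def trained_model(default_study):
    """Boundary + Platt model trained the prescribed way on the default
    study (outlier-filtered week-4 distal records)."""
    from nervedki.classifier import train_from_records
    from nervedki.slicewise import filter_outliers

    kept, _ = filter_outliers(default_study.records)
    boundary, platt, samples = train_from_records(
        kept, seed=1, n_boot=300
    )
    return boundary, platt, samples


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
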