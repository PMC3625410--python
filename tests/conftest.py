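import numpy as np
import pytest

from gxescreen.cohort_io import ExposurePanel, transform_exposures
from gxescreen.synthetic_cohort import generate_cohort, study_spec


@pytest.fixture(scope="session")
def study_cohort():
    """One study-structured cohort (18 SNPs, 5 exposures, missingness)
    shared across tests: raw frame, standardized frame, design, spec."""
    spec = study_spec(n_participants=5000, seed=1)
    syn = generate_cohort(spec)
    panel = ExposurePanel(columns=spec.exposure_ids)
    prepared = transform_exposures(syn.cohort, panel)
    return {
        "spec": spec,
        "raw": syn.cohort,
        "prepared": prepared,
        "design": syn.design,
        "panel": panel,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
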