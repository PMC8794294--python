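import numpy as np
import pytest

from nirspipe.io import PatientRecord
from nirspipe.montage import default_montage
from nirspipe.optics import load_extinction_table
from nirspipe.pipeline import scaled_cohort_config
from nirspipe.simulate import simulate_cohort, simulate_session


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def extinction():
    return load_extinction_table()


@pytest.fixture(scope="session")
def sim_session(montage, extinction):
    """One simulated session (right knee, no nerve block) at desk scale."""
    cfg = scaled_cohort_config(11)
    rng = np.random.default_rng(11)
    patient = PatientRecord("p1", 18.0, "F", "R", nerve_block=False,
                            pain_procedures=3)
    return simulate_session(patient, montage, cfg, rng, extinction)


@pytest.fixture(scope="session")
def small_cohort(montage, extinction):
    """A 6-patient cohort (small but valid for group statistics)."""
    cfg = scaled_cohort_config(21, n_patients=6)
    return simulate_cohort(cfg, montage, extinction)
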