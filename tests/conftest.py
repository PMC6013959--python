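import numpy as np
import pytest

from readmitnet.synthetic import AdmissionRecord, CohortConfig, generate_cohort

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_stay(pid="p1", admit=0, discharge=5, planned=False, disposition="routine",
              principal="P00", **kw):
    return AdmissionRecord(patient_id=pid, admit_date=admit, discharge_date=discharge,
                           planned=planned, disposition=disposition,
                           principal_code=principal, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    """A deterministic ~700-admission cohort with planted linear and XOR
    signal, shared across read-only tests."""
    cfg = CohortConfig(n_patients=300, seed=11,
                       linear_weights=(1.5, -1.0, 0.8),
                       nonlinear_pairs=((4, 5, 2.0),))
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
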