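import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strong_cohort_features():
    """Feature table of the strong-effect study cohort (10 users x 30 days),
    extracted once through the full raw-file chain and shared by the
    acceptance tests."""
    from stresspipe.pipeline import features_table
    from stresspipe.synth import CohortSpec, generate_cohort

    records, truth = generate_cohort(CohortSpec(n_users=10, n_days=30, seed=20120601))
    sessions = {
        (r.subject_id, r.date.isoformat()): r.rr for r in records if r.rr is not None
    }
    days = {(r.subject_id, r.date.isoformat()): r.phone for r in records}
    reports = {(r.subject_id, r.date.isoformat()): r.report for r in records}
    df = features_table(sessions, days, reports)
    return df, truth
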