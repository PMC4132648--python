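import numpy as np
import pytest

from ebm.event_distributions import LikelihoodTables
from ebm.synthetic_data import SimulationScenario, generate_cohort


def make_tables(rng, n_subjects, n_events):
    """Random strictly-positive likelihood tables for oracle tests."""
    le = rng.uniform(0.05, 2.0, size=(n_subjects, n_events))
    ln = rng.uniform(0.05, 2.0, size=(n_subjects, n_events))
    return LikelihoodTables(
        like_event=le,
        like_noevent=ln,
        log_like_event=np.log(le),
        log_like_noevent=np.log(ln),
        biomarker_names=[f"bm{i}" for i in range(n_events)],
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 6-event cohort with ground truth (session-cached)."""
    sc = SimulationScenario(
        n_events=6, separation=3.0, n_cn=60, n_mci=80, n_ad=40, seed=11
    )
    ds, truth = generate_cohort(sc)
    return sc, ds, truth
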