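import numpy as np
import pytest

from somaprf import (
    BodyPartSet,
    FitOptions,
    build_event_schedule,
    canonical_hrf,
    condition_regressors,
    design_matrix,
)


@pytest.fixture(scope="session")
def protocol():
    """Full experimental protocol: schedule, design (T=856), HRF, regressors."""
    schedule = build_event_schedule(seed=11)
    design = design_matrix(schedule)
    hrf = canonical_hrf()
    return schedule, design, hrf, condition_regressors(design, hrf)


@pytest.fixture(scope="session")
def small_protocol():
    """Tiny 4-condition single-run protocol (T=60 volumes at TR 2 s)."""
    parts = BodyPartSet(
        labels=("a", "b", "c", "d"),
        run_assignment={"a": 1, "b": 1, "c": 1, "d": 1},
    )
    schedule = build_event_schedule(
        parts,
        repetitions=2,
        base_iti=8.0,
        long_iti=12.0,
        seed=5,
        run_durations=((120.0,), (120.0,)),
    )
    design = design_matrix(schedule, volumes_per_run=(60,), tr=2.0, boxcar=3.0,
                           n_conditions=4)
    hrf = canonical_hrf(tr=2.0)
    return schedule, design, hrf, condition_regressors(design, hrf)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
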