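import numpy as np
import pytest

from dbsnet.aal import AAL90_LABELS, MOTOR_LABELS, MotorROISet
from dbsnet.synthetic import CohortSpec, generate_fc_cohort


def small_motor_rois(n: int = 14) -> MotorROISet:
    return MotorROISet(labels=MOTOR_LABELS, indices=tuple(range(n)))


@pytest.fixture(scope="session")
def aal_motor_rois() -> MotorROISet:
    return MotorROISet.from_labels(list(AAL90_LABELS))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort under the study conditions (n=43, 90 ROIs)."""
    return generate_fc_cohort(CohortSpec(seed=101))


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for mechanics tests (n=16, 24 ROIs)."""
    return generate_fc_cohort(CohortSpec(n_subjects=16, roi_count=24, seed=202))


def covariates_of(cohort) -> np.ndarray:
    meta = cohort.metadata
    return np.column_stack(
        [meta["age"].to_numpy(float), (meta["gender"] == "F").to_numpy(float)]
    )
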