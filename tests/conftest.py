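import numpy as np
import pandas as pd
import pytest

from gazecone import CohortSpec, ObserverParams, simulate_cohort
from gazecone.io import DESIGN_AZIMUTHS, TRIAL_COLUMNS


@pytest.fixture(scope="session")
def small_exp1():
    """A small mixed-ethnicity exp1 cohort with ground truth."""
    spec = CohortSpec(n_participants={"white": 4, "east_asian": 4},
                      design="exp1", seed=42)
    trials, truth = simulate_cohort(spec, ObserverParams())
    return trials, truth


@pytest.fixture(scope="session")
def small_exp2():
    spec = CohortSpec(n_participants={"white": 6}, design="exp2", seed=7)
    trials, truth = simulate_cohort(spec, ObserverParams())
    return trials, truth


def make_count_table(pid="p0", condition="eyes_closed", n_per_az=10,
                     fills=None):
    """Tidy count table for one participant-condition.

    ``fills``: dict azimuth -> (n_left, n_middle, n_right); unspecified
    azimuths get an ideal observer (left below -10, middle to +10, right
    above).
    """
    rows = []
    for az in DESIGN_AZIMUTHS:
        if fills and az in fills:
            nl, nm, nr = fills[az]
        elif az <= -20:
            nl, nm, nr = n_per_az, 0, 0
        elif az >= 20:
            nl, nm, nr = 0, 0, n_per_az
        else:
            nl, nm, nr = 0, n_per_az, 0
        rows.append({"participant_id": pid, "condition": condition,
                     "azimuth_deg": az, "n_left": nl, "n_middle": nm,
                     "n_right": nr, "n_total": nl + nm + nr})
    return pd.DataFrame(rows)


def counts_from_params(params, n_total=1000, azimuths=DESIGN_AZIMUTHS,
                       pid="p0", condition="eyes_closed"):
    """Rounded expected counts under the three-category logistic model."""
    from gazecone import predict_proportions
    rows = []
    for az in azimuths:
        pL, pM, pR = predict_proportions(params, az)
        nl = int(round(float(pL) * n_total))
        nr = int(round(float(pR) * n_total))
        nm = n_total - nl - nr
        rows.append({"participant_id": pid, "condition": condition,
                     "azimuth_deg": az, "n_left": nl, "n_middle": nm,
                     "n_right": nr, "n_total": n_total})
    return pd.DataFrame(rows)


def make_vigilance(pid, n=12, n_failed=0, ethnicity="white"):
    rows = []
    for i in range(n):
        rows.append({
            "participant_id": pid, "ethnicity": ethnicity, "condition": None,
            "trial_type": "vigilance_auditory" if i < n // 2 else "vigilance_visual",
            "azimuth_deg": None, "response": None,
            "vigilance_correct": i >= n_failed})
    # object dtype throughout so concat with experimental frames (where
    # these columns are all-NA) does not warn about dtype inference
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS, dtype=object)


def make_experimental(pid, condition="eyes_closed", responses=None,
                      ethnicity="white", n_per_az=10):
    """Experimental trials; ``responses``: dict azimuth -> list of responses
    (defaults to an ideal observer with middle between ±10)."""
    rows = []
    for az in DESIGN_AZIMUTHS:
        if responses and az in responses:
            rs = responses[az]
        else:
            r = "left" if az <= -20 else ("right" if az >= 20 else "middle")
            rs = [r] * n_per_az
        for resp in rs:
            rows.append({"participant_id": pid, "ethnicity": ethnicity,
                         "condition": condition, "trial_type": "experimental",
                         "azimuth_deg": az, "response": resp,
                         "vigilance_correct": None})
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)
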