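import numpy as np
import pandas as pd
import pytest

from bnorms import Config, LongitudinalTable, SimParams, simulate_cohort


@pytest.fixture(scope="session")
def cfg():
    return Config()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest mixed-sex cohort shared by read-only tests."""
    params = SimParams(n_subjects=200, n_rois=6, n_sites=3, y4_missing_frac=0.5)
    table, truth = simulate_cohort(params, seed=11)
    return table, truth


def make_table(rows):
    """Build a LongitudinalTable from a list of dicts, filling defaults."""
    defaults = dict(
        family_id=None, sex="F", site_id="site00", bmi=18.0,
        euler_number=-60, pds_mean=2.0,
    )
    full = []
    for r in rows:
        d = dict(defaults)
        d.update(r)
        full.append(d)
    return LongitudinalTable(pd.DataFrame(full), validate=False)


@pytest.fixture
def tiny_table():
    """Three subjects, hand-built, with one ROI."""
    rows = []
    for i, sid in enumerate(["S1", "S2", "S3"]):
        for v, age in (("baseline", 118 + i), ("y2", 142 + i)):
            rows.append({
                "subject_id": sid, "visit": v, "age_months": float(age),
                "ct_L_roi000": 2.5 + 0.01 * i,
            })
    return make_table(rows)
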