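import numpy as np
import pandas as pd
import pytest

import casemix as cm


@pytest.fixture(scope="session")
def small_spec():
    return cm.CohortSpec(n_patients=2000, seed=11, n_categories=6,
                         codes_per_category=6)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    code_map = cm.build_code_universe(small_spec)
    cohort, truth = cm.sample_cohort(small_spec, code_map)
    return cohort, truth, code_map


def make_patients(rows):
    """Patient table from (patient_id, age, sex, codes, cost) tuples;
    codes may be a list or a semicolon-joined string."""
    recs = []
    for pid, age, sex, codes, cost in rows:
        if not isinstance(codes, str):
            codes = ";".join(codes)
        recs.append({"patient_id": pid, "age": age, "sex": sex,
                     "codes": codes, "cost": float(cost)})
    return pd.DataFrame(recs)


def random_design(rng, n, p, intercept=True):
    X = rng.normal(size=(n, p))
    if intercept:
        X[:, 0] = 1.0
    return X
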