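import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def tiny_cohort() -> pd.DataFrame:
    """Six persons, two eyes each, hand-written values for exact assertions."""
    rows = []
    spec = [
        # pid, age, sex, edu, lens, se_od, se_os, al_od, al_os
        ("P1", 55, "female", 12.0, "phakic", -1.0, -2.0, 23.5, 23.7),
        ("P2", 65, "male", 16.0, "phakic", -3.0, -3.5, 25.0, 25.2),
        ("P3", 70, "female", 9.0, "phakic", 1.0, 0.5, 22.8, 22.9),
        ("P4", 71, "male", 13.0, "phakic", 0.5, 0.0, 23.2, 23.1),
        ("P5", 48, "female", 18.0, "pseudophakic", -0.5, -1.0, 24.0, 24.1),
        ("P6", 60, "male", 11.0, "phakic", 2.0, 1.5, 22.5, 22.6),
    ]
    for pid, age, sex, edu, lens, se_od, se_os, al_od, al_os in spec:
        for eye, se, al in (("OD", se_od, al_od), ("OS", se_os, al_os)):
            rows.append(
                dict(
                    person_id=pid, age=age, sex=sex, education_years=edu,
                    school_level=None, vocational_level=None, eye=eye,
                    se=se, al=al, acd=3.2, cc=7.8, lt=4.3, wtw=12.2,
                    lens_status=lens,
                )
            )
    return pd.DataFrame(rows)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
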