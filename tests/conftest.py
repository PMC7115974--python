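import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dbsdt.cohort_model import (
    Cohort,
    LimbStatus,
    NeurophysStatus,
    PatientRecord,
    default_schema,
)
from dbsdt.synthetic_cohort import default_params, generate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_record(
    id="P0",
    sex="M",
    etiology="acquired_cp",
    mri="normal",
    baseline_bfm=70.0,
    followup_bfm=None,
    pct_change=None,
    cmct="normal",
    sep="normal",
    **kw,
) -> PatientRecord:
    return PatientRecord(
        id=id,
        sex=sex,
        etiology=etiology,
        mri=mri,
        baseline_bfm=baseline_bfm,
        followup_bfm=followup_bfm,
        pct_change=pct_change,
        cmct=NeurophysStatus(cmct),
        sep=NeurophysStatus(sep),
        **kw,
    )


def make_cohort(records, labels=None) -> Cohort:
    return Cohort(list(records), default_schema(), labels)


@pytest.fixture(scope="session")
def small_cohort() -> Cohort:
    """Three handcrafted records exercising limbs, NA and both outcomes."""
    recs = [
        make_record(
            id="A",
            etiology="isolated_genetic",
            baseline_bfm=100.0,
            followup_bfm=70.0,
            cmct="normal",
            cmct_limbs=(LimbStatus.NORMAL,) * 4,
        ),
        make_record(
            id="B",
            sex="F",
            baseline_bfm=60.0,
            followup_bfm=66.0,
            cmct="abnormal",
            cmct_limbs=(LimbStatus.ABNORMAL, LimbStatus.NORMAL),
            mri="abnormal",
        ),
        make_record(
            id="C",
            etiology="acquired_other",
            baseline_bfm=40.5,
            pct_change=12.5,
            cmct="NA",
            cmct_limbs=(LimbStatus.UNSATISFACTORY, LimbStatus.UNSATISFACTORY),
        ),
    ]
    return make_cohort(recs)


@pytest.fixture(scope="session")
def default_cohort() -> Cohort:
    """Default synthetic acquired-dystonia cohort (n = 96), fixed seed."""
    return generate_cohort(default_params(), seed=20)


@pytest.fixture(scope="session")
def big_cohort() -> Cohort:
    """Large synthetic cohort for law-of-large-numbers checks."""
    params = default_params()
    params.n = 10_000
    return generate_cohort(params, seed=7)


@pytest.fixture(scope="session")
def strong_effect_cohort() -> Cohort:
    """n = 500 cohort with strong planted CMCT + severity effects and
    noise features (sex, MRI), for planted-structure recovery checks."""
    params = default_params()
    params.n = 500
    params.beta_cmct = -30.0
    params.beta_sev = 0.8
    params.noise_sd = 10.0
    return generate_cohort(params, seed=11)
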