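"""Shared fixtures: published worked-example patients and strategies."""

import pytest
from hypothesis import strategies as st

from strokedam import PatientProfile, prepare_profile

# Nine worked-example patients with the published percentages:
# untreated/treated P(mRS<=1) from the original instrument, P(mRS>=5),
# untreated/treated P(mRS<=2) and P(death) from the decision model, and
# the SICH risk (percent).  Row 4 is the known-irreproducible
# prior-stroke patient; rows 5 and 8 print a lower SICH class than their
# point totals imply (both documented in the methods note).
TABLE3 = [
    dict(age=77, male=0, diabetes=1, prior_stroke=0, sbp=140, glucose=15.2, nihss=5,
         ott=179, stpi_untreated=48, stpi_treated=72, severe=13,
         dam_untreated=54, dam_treated=69, dam_dead=12, sich=3.14),
    dict(age=57, male=1, diabetes=1, prior_stroke=0, sbp=179, glucose=20.7, nihss=5,
         ott=164, stpi_untreated=51, stpi_treated=56, severe=7,
         dam_untreated=73, dam_treated=76, dam_dead=9, sich=3.14),
    dict(age=73, male=0, diabetes=0, prior_stroke=0, sbp=160, glucose=7.1, nihss=10,
         ott=113, stpi_untreated=36, stpi_treated=63, severe=12,
         dam_untreated=51, dam_treated=69, dam_dead=9, sich=3.14),
    dict(age=76, male=0, diabetes=1, prior_stroke=1, sbp=140, glucose=15.7, nihss=12,
         ott=170, stpi_untreated=21, stpi_treated=27, severe=28,
         dam_untreated=21, dam_treated=24, dam_dead=26, sich=3.72),
    dict(age=73, male=0, diabetes=0, prior_stroke=0, sbp=170, glucose=6.4, nihss=16,
         ott=89, stpi_untreated=13, stpi_treated=30, severe=24,
         dam_untreated=29, dam_treated=41, dam_dead=17, sich=3.14),
    dict(age=64, male=1, diabetes=0, prior_stroke=0, sbp=169, glucose=7.4, nihss=18,
         ott=175, stpi_untreated=16, stpi_treated=21, severe=22,
         dam_untreated=34, dam_treated=37, dam_dead=17, sich=3.14),
    dict(age=75, male=1, diabetes=0, prior_stroke=0, sbp=169, glucose=7.2, nihss=19,
         ott=165, stpi_untreated=10, stpi_treated=13, severe=35,
         dam_untreated=26, dam_treated=28, dam_dead=26, sich=3.72),
    dict(age=77, male=1, diabetes=0, prior_stroke=0, sbp=150, glucose=4.7, nihss=19,
         ott=90, stpi_untreated=10, stpi_treated=20, severe=33,
         dam_untreated=25, dam_treated=31, dam_dead=23, sich=3.14),
    dict(age=51, male=0, diabetes=0, prior_stroke=0, sbp=165, glucose=13.1, nihss=29,
         ott=122, stpi_untreated=4, stpi_treated=9, severe=51,
         dam_untreated=8, dam_treated=10, dam_dead=47, sich=5.05),
]

_COVARIATE_KEYS = ("age", "male", "diabetes", "prior_stroke", "sbp", "glucose",
                   "nihss", "ott")


def table3_profile(row: dict) -> PatientProfile:
    """Validated, imputed profile for one worked-example row."""
    return prepare_profile(
        PatientProfile(**{k: row[k] for k in _COVARIATE_KEYS})
    )


@pytest.fixture(scope="session")
def table3():
    return TABLE3


@pytest.fixture(scope="session")
def table3_profiles():
    return [table3_profile(row) for row in TABLE3]


@pytest.fixture(scope="session")
def reference_patient():
    """The sensitivity-analysis reference case: 70-year-old non-diabetic
    man, no prior stroke, SBP 140, glucose 6.5, NIHSS 14, treated at 90
    min, no infarct sign on the pre-treatment scan."""
    return prepare_profile(
        PatientProfile(age=70, male=1, diabetes=0, prior_stroke=0, sbp=140,
                       glucose=6.5, nihss=14, ott=90, infarct_sign=0)
    )


def valid_profiles() -> st.SearchStrategy:
    """Hypothesis strategy over the model's validated input box."""
    indicator = st.sampled_from([0.0, 1.0])
    return st.builds(
        PatientProfile,
        age=st.floats(18, 100),
        male=indicator,
        diabetes=indicator,
        prior_stroke=indicator,
        sbp=st.floats(80, 200),
        glucose=st.floats(2.0, 25.0),
        nihss=st.integers(0, 42).map(float),
        ott=st.floats(0, 270),
        infarct_sign=st.floats(0, 1),
        weight_kg=st.floats(40, 150),
        aspirin=indicator,
        clopidogrel=indicator,
        hypertension=indicator,
        chf=indicator,
    )
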