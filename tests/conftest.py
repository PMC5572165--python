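import logging

import pytest

from ocpanel import CohortDesign, simulate_cohort
from ocpanel.cohort import Cohort, Group, Sample, Subject, Subtype

logging.getLogger("ocpanel").setLevel(logging.WARNING)


def make_sample(sample_id, subject_id, tdx, **markers):
    base = {m: None for m in ("igfbp2", "lcat", "shbg", "grp78", "calprotectin", "ca125")}
    base.update(markers)
    return Sample(sample_id=sample_id, subject_id=subject_id, tdx_days=tdx, markers=base)


@pytest.fixture
def tiny_cohort():
    """One Type II case with two serial samples and one matched control."""
    subjects = [
        Subject("case-1", Group.CASE, Subtype.TYPE2, raw_subtype="type2",
                survival_days=700.0, death_event=True, bmi=26.5),
        Subject("ctrl-1", Group.CONTROL, matched_case_id="case-1", ocp_ever=True),
    ]
    samples = [
        make_sample("s1", "case-1", 100.0, igfbp2=90.0, lcat=7.5, shbg=20.0, ca125=60.0),
        make_sample("s2", "case-1", 1200.0, igfbp2=50.0, lcat=12.0, shbg=30.0, ca125=12.0),
        make_sample("s3", "ctrl-1", 150.0, igfbp2=40.0, lcat=14.0, shbg=40.0, ca125=10.0),
    ]
    return Cohort(subjects=subjects, samples=samples)


@pytest.fixture(scope="session")
def default_cohort():
    """One realization of the default synthetic study design."""
    return simulate_cohort(CohortDesign(seed=7))


@pytest.fixture(scope="session")
def default_design():
    return CohortDesign(seed=7)
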