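import numpy as np
import pytest

import thermoapos as ta


@pytest.fixture(scope="session")
def phantom():
    """Default noisy phantom with ground truth."""
    return ta.generate_phantom(seed=1)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free phantom: every zone is exactly base + offset."""
    return ta.generate_phantom(ta.PhantomSpec(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def filtered_phantom(phantom):
    return ta.filter_background(phantom.fld)


@pytest.fixture(scope="session")
def roiset(filtered_phantom, phantom):
    return ta.segment(filtered_phantom, phantom.anchors)


@pytest.fixture(scope="session")
def cohort43_report():
    """Full pipeline on the default-size simulated cohort (43 + 43)."""
    cohort = ta.generate_cohort(ta.CohortSpec(), seed=20260924)
    case = [ta.SubjectInput(s.subject_id, s.phantom.fld, s.phantom.anchors)
            for s in cohort if s.group == "case"]
    control = [ta.SubjectInput(s.subject_id, s.phantom.fld, s.phantom.anchors)
               for s in cohort if s.group == "control"]
    return ta.run_pipeline(case, control)


def random_field(rng, rows=6, cols=7, lo=20.0, hi=40.0):
    return ta.TemperatureField(rng.uniform(lo, hi, size=(rows, cols)))
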