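import pytest

from ploidyscope import synthetic


@pytest.fixture(scope="session")
def study_cohort_df():
    """Per-case table of the packaged 602-case study cohort."""
    spec, _ = synthetic.load_study_cohort()
    rows = synthetic.generate_cohort(spec, seed=0)
    return synthetic.cohort_to_frame(rows)


@pytest.fixture(scope="session")
def study_payload():
    return synthetic.load_study_cohort()[1]
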