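import dataclasses

import pytest

from geekdex import gi, synth


@pytest.fixture(scope="session")
def small_cohort():
    """A scored 400-family cohort with active paternal-age, SES and
    attainment effects; shared across read-only tests."""
    cfg = dataclasses.replace(synth.paper_fit_preset(), n_families=400, seed=101)
    return gi.score_cohort(synth.simulate_cohort_frame(cfg))


@pytest.fixture(scope="session")
def null_cohort():
    """A scored cohort with no generated effects at all."""
    cfg = dataclasses.replace(
        synth.SimConfig(),
        n_families=400,
        seed=202,
    )
    return gi.score_cohort(synth.simulate_cohort_frame(cfg))
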