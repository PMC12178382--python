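import numpy as np
import pytest
from hypothesis import settings

from wsibpg.experiment import prepare_bpg_from_truth
from wsibpg.synthetic import CohortSpec, generate_cohort, reference_cohort_spec

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort with the default two-population structure."""
    spec = CohortSpec(
        n_slides=36, feature_dim=32, bag_size_range=(20, 40), seed=7
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def reference_cohort():
    """The fixed study-condition cohort used by the evaluation harness."""
    return generate_cohort(reference_cohort_spec(seed=1))


@pytest.fixture(scope="session")
def reference_bpg(reference_cohort):
    model, ref_slide = prepare_bpg_from_truth(
        reference_cohort.bags, reference_cohort.patch_truth, seed=1
    )
    return model
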