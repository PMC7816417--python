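import numpy as np
import pytest

from perfconcord.synthetic_cohort import SubjectTruth


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tumor_truth():
    """A subject at the published tumor medians."""
    return SubjectTruth(
        subject_id="S01", region="tumor", latent_v=0.0,
        f_true=0.101, D_true=1.2e-3, Dstar_true=17.4e-3,
        BF_true=38.9, BV_true=2.4, PEM_true=17.8,
        MVD_true=33.2, MVA_true=0.014,
    )
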