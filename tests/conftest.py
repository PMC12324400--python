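import numpy as np
import pandas as pd
import pytest

from colam.synthetic import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully separated cohort: every signature gene is a perfect step."""
    spec = SyntheticSpec(
        n_per_group=10,
        n_inflammatory=5,
        n_noninflammatory=5,
        n_background=30,
        noise_sd=0.2,
        effect=1.0,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture
def toy_matrix():
    """3-gene x 4-sample matrix with hand-checkable values."""
    return pd.DataFrame(
        {
            "s1": [2.0, 10.0, 5.0],
            "s2": [4.0, 12.0, 5.0],
            "s3": [6.0, 14.0, 7.0],
            "s4": [8.0, 16.0, 7.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
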