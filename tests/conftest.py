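import numpy as np
import pytest

from cacaopheno import SimConfig, generate_trial


@pytest.fixture(scope="session")
def small_trial():
    """Compact trial: 20 accessions, 4 planted clusters, 3 traits + 2
    qualitative descriptors, well separated."""
    cfg = SimConfig(
        n_accessions=20,
        n_reps=3,
        K_true=4,
        separation=5.0,
        traits={
            "FM": (767.3, 53286.7, 4000.0),
            "SI": (1.28, 0.03, 0.004),
            "PI": (20.57, 8.0, 1.0),
        },
        correlations={("SI", "PI"): -0.3},
        qual_traits=["SC", "FS"],
        seed=11,
    )
    return generate_trial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
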