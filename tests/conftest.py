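import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def small_observations():
    """Three genotypes, hand-written roots with known counts."""
    from rootstage import RootObservation, StageCountVector

    def root(rid, g, length, counts, positions=None):
        return RootObservation(
            root_id=rid,
            genotype=g,
            pr_length_cm=length,
            emerged_count=counts[-1],
            stage_counts=StageCountVector(tuple(counts)),
            lr_positions_cm=positions,
        )

    return [
        root("a1", "Col0", 5.0, [1, 0, 0, 0, 0, 0, 0, 2], positions=(1.0, 3.0)),
        root("a2", "Col0", 4.0, [0, 1, 0, 0, 0, 0, 0, 0]),
        root("b1", "mutant", 6.0, [0, 0, 0, 0, 0, 0, 1, 3], positions=(0.5, 1.5, 3.5)),
        root("c1", "oe", 5.5, [2, 2, 0, 0, 0, 0, 0, 0]),
        root("c2", "oe", 3.0, [0, 0, 0, 0, 0, 0, 0, 0]),  # zero-LRP root is legal
    ]
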