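import numpy as np
import pytest

from pitgrowth import synthetic as syn
from pitgrowth import features as feat


@pytest.fixture(scope="session")
def default_table():
    """One default-replicate feature table (3 subjects x 20 sessions)."""
    return syn.simulate_feature_table(syn.TrajectoryTruth(seed=3))


@pytest.fixture(scope="session")
def centered_table(default_table):
    return feat.add_person_centered_columns(default_table)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise- and warp-free default phantom (image, labels, spec)."""
    spec = syn.PhantomSpec(noise_sd=0.0, deformation_scale_mm=0.0)
    img, lab = syn.render_session(spec)
    return spec, img, lab


def replicate_seeds(n: int, base: int = 0) -> list[int]:
    """Canonical replicate seed stream used across simulation tests."""
    return [int(s % (2**31)) for s in np.random.SeedSequence(base).generate_state(n)]
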