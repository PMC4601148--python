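import numpy as np
import pytest

import fociquant as fq


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def clean_scene():
    """Noise-free counting-scale scene with 10 nuclei x 10 separated foci."""
    spec = fq.default_counting_spec(n_nuclei=10, seed=11)
    stack, truth = fq.generate_scene(spec)
    return spec, stack, truth


@pytest.fixture(scope="session")
def clean_mask(clean_scene):
    _spec, stack, _truth = clean_scene
    return fq.segment_nuclei(stack.channel("dna"))
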