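import numpy as np
import pytest

import junctiongraph as jg


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def three_way_junction():
    """3-way junction: b=(5,5,5), loops (0,4,4)."""
    ss = jg.parse_dotbracket(jg.make_junction_ss([5, 5, 5], [0, 4, 4]))
    return jg.find_junctions(ss)[0]


@pytest.fixture
def four_way_junction():
    """4-way junction: b=(5,4,6,5), loops (2,0,3,0)."""
    ss = jg.parse_dotbracket(jg.make_junction_ss([5, 4, 6, 5], [2, 0, 3, 0]))
    return jg.find_junctions(ss)[0]


def junction_with(bp_counts, loop_lens):
    ss = jg.parse_dotbracket(jg.make_junction_ss(bp_counts, loop_lens))
    junctions = jg.find_junctions(ss)
    assert len(junctions) == 1
    return junctions[0]


def random_rotation(rng):
    """Uniform-ish random proper rotation via QR decomposition."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q
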