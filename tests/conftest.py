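import numpy as np
import pytest

import seqscale as ss


@pytest.fixture(scope="session")
def hexamer_mask():
    return ss.parse_mask("NNNCNNN")


@pytest.fixture(scope="session")
def small_genome():
    """2 kb random genome with near-complete mappability at read length 36."""
    return {"chr1": ss.generate_genome(2000, seed=7)}


@pytest.fixture(scope="session")
def repeat_genome():
    """Genome with an exact planted 60 bp repeat to exercise unmappability."""
    rng = np.random.default_rng(8)
    core = ss.generate_genome(1500, seed=9)
    repeat = ss.generate_genome(60, seed=10)
    return {"chr1": core[:500] + repeat + core[500:1000] + repeat + core[1000:]}


def random_sequence(length, seed):
    return ss.generate_genome(length, seed=seed)
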