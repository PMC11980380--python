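import numpy as np
import pytest

from silentbias.genetic_code import build_standard_code


@pytest.fixture(scope="session")
def code():
    return build_standard_code()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cds(rng, n_codons, code, include_stop=True):
    """Random in-frame CDS over sense codons (helper for oracle tests)."""
    sense = list(code.sense_codons)
    body = "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))
    return body + ("TAA" if include_stop else "")
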