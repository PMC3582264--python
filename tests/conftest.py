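import itertools

import pytest

from adpkit import alignment_app, flowgram_app, nussinov_app


@pytest.fixture(scope="session")
def ali():
    return alignment_app()


@pytest.fixture(scope="session")
def nus():
    return nussinov_app()


@pytest.fixture(scope="session")
def flow():
    return flowgram_app()


def all_strings(alphabet: str, max_len: int):
    """All strings over ``alphabet`` of length 0..max_len, shortest first."""
    out = [""]
    for n in range(1, max_len + 1):
        out.extend("".join(t) for t in itertools.product(alphabet, repeat=n))
    return out
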