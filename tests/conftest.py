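import numpy as np
import pytest

from agpepscan import synthdata


@pytest.fixture
def write(tmp_path):
    """Write text to a temp file and return its path."""

    def _write(name: str, text: str):
        p = tmp_path / name
        p.write_text(text)
        return p

    return _write


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_proteome():
    """5 planted AG peptides among 20 decoys, with the truth rows."""
    return synthdata.gen_proteome(5, 20, seed=1)
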