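import numpy as np
import pytest

from editscope import synthetic_data as sd
from editscope.io_formats import SampleDesign


@pytest.fixture(scope="session")
def small_reference():
    return sd.make_reference(n_transcripts=2, length=400, gc=0.5, seed=11)


@pytest.fixture(scope="session")
def design_3v3():
    return [SampleDesign(f"wt{i}", "WT") for i in range(3)] + [
        SampleDesign(f"ko{i}", "KO") for i in range(3)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def a_positions(seq: str, lo: int = 0, hi: int | None = None) -> list[int]:
    hi = len(seq) if hi is None else hi
    return [i for i, b in enumerate(seq) if b == "A" and lo <= i < hi]


def t_positions(seq: str, lo: int = 0, hi: int | None = None) -> list[int]:
    hi = len(seq) if hi is None else hi
    return [i for i, b in enumerate(seq) if b == "T" and lo <= i < hi]
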