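import numpy as np
import pytest

from midakit import MetaboliteRecord, parse_ls_record

ALANINE_LINE = (
    "Alanine (Ala)\t"
    "259.15#260.1#261.1#262.1#263.1#264.1#265.1#\t"
    "0.07#8.53#2.3#2.39#44.59#8.79#3.88#\t"
    "3\t3"
)


@pytest.fixture
def alanine_line() -> str:
    return ALANINE_LINE


@pytest.fixture
def alanine_record() -> MetaboliteRecord:
    return parse_ls_record(ALANINE_LINE)


def brute_force_convolve(a, b):
    """Independent O(n*m) convolution oracle (explicit double loop)."""
    a, b = list(a), list(b)
    out = [0.0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            out[i + j] += ai * bj
    return np.array(out)


def forward_substitution(L, b):
    """Independent oracle for square lower-triangular systems."""
    L = np.asarray(L, dtype=float)
    b = np.asarray(b, dtype=float)
    n = len(b)
    x = np.zeros(n)
    for i in range(n):
        x[i] = (b[i] - sum(L[i, j] * x[j] for j in range(i))) / L[i, i]
    return x
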