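import numpy as np
import pytest

from coilscan.synthetic import CrickParams, crick_backbone


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def parallel_dimer():
    """Default heptad parallel dimer, 28 residues per chain."""
    return crick_backbone(CrickParams.for_bundle(2, 28, parallel=True))


@pytest.fixture
def antiparallel_dimer():
    return crick_backbone(CrickParams.for_bundle(2, 28, parallel=False))


def windows_oracle(n: int, length: int, overlap: int) -> list[tuple[int, int]]:
    """Independent brute-force enumerator of the windowing rule.

    Walk windows left to right; whenever the next window would not end
    strictly before the C-terminus, anchor the final window at the terminus
    (window length takes priority, overlap grows).
    """
    if n < length:
        return [(0, n)]
    out = []
    s = 0
    while s + length < n:
        out.append((s, s + length))
        s += length - overlap
    out.append((n - length, n))
    return out
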