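import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fissionkit import load_packaged_ese_matrices
from fissionkit.snd import SNDRecord


@pytest.fixture(scope="session")
def ese_matrices():
    return load_packaged_ese_matrices()


def make_snds(positions, ws, lineage="query", chrom="chr1"):
    """Build SNDRecords with bases consistent with the requested ws labels."""
    out = []
    for p, w in zip(positions, ws):
        if lineage == "query":
            t, q, o = ("A", "G", "A") if w else ("C", "T", "C")
        else:
            t, q, o = ("G", "A", "A") if w else ("T", "C", "C")
        out.append(SNDRecord(chrom, int(p), t, q, o, lineage, bool(w)))
    return out


@pytest.fixture
def snd_builder():
    return make_snds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
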