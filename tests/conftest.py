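import numpy as np
import pytest

from risipipe.reference_io import FeatureInterval, RrnaReference
from risipipe.synthetic import make_reference
from risipipe.tailseq import FORWARD_PRIMERS


@pytest.fixture(scope="session")
def toy_ref() -> RrnaReference:
    """Random toy reference (pre-rRNA unit + 5S + decoys), fixed seed."""
    return make_reference(seed=1)


def _fixed_seq(n: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def make_tail_ref(downstream: str, mid_len: int = 35, seed: int = 7) -> RrnaReference:
    """Hand-built single-transcript reference for controlled tail tests.

    Layout: 30 nt junk | 26S forward primer | ``mid_len`` nt | mature 26S
    3' end | ``downstream`` (first bases chosen by the test) | junk.
    """
    primer = FORWARD_PRIMERS["26S"]
    up = _fixed_seq(30, seed)
    mid = _fixed_seq(mid_len, seed + 1)
    # keep the 3 bases before the boundary unambiguous (never U)
    mid = mid[:-3] + "ACG"
    tail_pad = _fixed_seq(40, seed + 2)
    seq = up + primer + mid + downstream + tail_pad
    end = len(up) + len(primer) + len(mid)
    feats = [
        FeatureInterval("pre-rRNA", "26S", 0, end),
        FeatureInterval("pre-rRNA", "ETS3", end, len(seq)),
    ]
    return RrnaReference(transcripts={"pre-rRNA": seq}, features=feats)


@pytest.fixture()
def tail_ref_gc() -> RrnaReference:
    """Tail-test reference whose downstream context starts 'GC' (non-U)."""
    return make_tail_ref("GCAC" + _fixed_seq(30, 11))


@pytest.fixture()
def tail_ref_t() -> RrnaReference:
    """Tail-test reference whose downstream context starts 'TC' (templated U)."""
    return make_tail_ref("TCAC" + _fixed_seq(30, 12))
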