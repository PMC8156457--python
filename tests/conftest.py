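import numpy as np
import pytest

from cfmito.haplogroup import packaged_tree
from cfmito.reference import MtReference, find_homopolymers, packaged_reference


@pytest.fixture(scope="session")
def ref():
    return packaged_reference()


@pytest.fixture(scope="session")
def tree():
    return packaged_tree()


@pytest.fixture(scope="session")
def snv_track(ref):
    return find_homopolymers(ref, 4)


@pytest.fixture(scope="session")
def indel_track_strict(ref):
    return find_homopolymers(ref, 3)


def brute_force_runs(seq: str, min_len: int, circular: bool = False):
    """Independent O(L) character-scan oracle for maximal homopolymer runs."""
    n = len(seq)
    runs = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and seq[j + 1] == seq[i]:
            j += 1
        runs.append([i + 1, j + 1, seq[i], j - i + 1])
        i = j + 1
    if circular and len(runs) > 1 and runs[0][2] == runs[-1][2]:
        head, tail = runs[0], runs[-1]
        runs = [[tail[0], head[1], head[2], head[3] + tail[3]]] + runs[1:-1]
    return sorted(
        [tuple(r) for r in runs if r[3] >= min_len], key=lambda r: r[0]
    )


@pytest.fixture()
def toy_ref():
    def make(seq: str, circular: bool = True) -> MtReference:
        return MtReference(name="toy", sequence=seq.upper(), circular=circular)

    return make
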