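import numpy as np
import pytest

from trieprofile import gc_model, make_model


@pytest.fixture(scope="session")
def binary_model():
    """Biased binary source p=(0.7, 0.3)."""
    return make_model([0.7, 0.3])


@pytest.fixture(scope="session")
def quaternary_model():
    """Degenerate DNA model with GC-content 0.6664 (p_C=p_G=0.3332)."""
    return gc_model(0.6664)


def naive_depth_profile(s: str) -> dict[int, int]:
    """Quadratic-DP oracle for shortest-unique-prefix lengths.

    Appends a sentinel smaller than any symbol, computes all pairwise
    suffix LCPs by the recurrence lcp[i,j] = eq(i,j) * (1 + lcp[i+1,j+1]),
    and takes depth(i) = 1 + max_{j != i} lcp[i,j].  Independent of the
    suffix-array code path.
    """
    arr = np.frombuffer((s + "\0").encode("latin-1"), dtype=np.uint8)
    L = arr.size
    eq = arr[:, None] == arr[None, :]
    lcp = np.zeros((L + 1, L + 1), dtype=np.int64)
    for i in range(L - 1, -1, -1):
        lcp[i, :L] = np.where(eq[i, :L], lcp[i + 1, 1 : L + 1] + 1, 0)
    lcp = lcp[:L, :L]
    np.fill_diagonal(lcp, -1)  # a suffix does not collide with itself
    depths = lcp.max(axis=1) + 1
    counts: dict[int, int] = {}
    for d in depths[: L - 1]:  # exclude the sentinel suffix
        counts[int(d)] = counts.get(int(d), 0) + 1
    return counts
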