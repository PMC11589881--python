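import pytest

from memtail import HydrophobicityScale, TMSegment, Topology


@pytest.fixture(scope="session")
def scale():
    return HydrophobicityScale.default()


def single_tm_topology(center: int, n_term_side: str = "in", tm_len: int = 19):
    """One-TM topology with the given floor-midpoint centre."""
    start = center - (tm_len - 1) // 2
    return Topology(
        segments=[TMSegment(start=start, end=start + tm_len - 1)],
        n_term_side=n_term_side,
    )


def multi_tm_topology(n_tm: int, n_term_side: str = "in", tm_len: int = 19,
                      loop_len: int = 10, offset: int = 10):
    segs = []
    pos = offset
    for _ in range(n_tm):
        segs.append(TMSegment(start=pos + 1, end=pos + tm_len))
        pos += tm_len + loop_len
    return Topology(segments=segs, n_term_side=n_term_side)
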