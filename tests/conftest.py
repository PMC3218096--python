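from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tandemsat.arrays import TandemArray

settings.register_profile(
    "ci", derandomize=True, max_examples=40,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


def build_array(seq: str, unit_len: int, *, source="fix",
                start: int = 1) -> TandemArray:
    """Wrap a raw sequence as a catalog entry for unit-level tests."""
    return TandemArray(
        source_seq_id=source, start=start, end=start + len(seq) - 1,
        unit_len=unit_len, copy_number=max(1.0, len(seq) / unit_len),
        consensus="N" * unit_len, array_seq=seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_seq(rng):
    def _make(n: int, gc: float = 0.5) -> str:
        p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
        return "".join(rng.choice(list("ACGT"), size=n, p=p))
    return _make
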