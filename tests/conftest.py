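import numpy as np
import pytest

from epimosaic import BasalTrace


def trace_from_string(s: str, source_id: str = "t") -> BasalTrace:
    """Build a trace from a compact string, e.g. 'PPN' -> POS,POS,NEG."""
    return BasalTrace(
        labels=np.array([ch == "P" for ch in s], dtype=bool),
        source_id=source_id,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240417)


@pytest.fixture
def balanced_trace():
    """Ten donor then ten host pixels: maximally contiguous at 10/10."""
    return trace_from_string("P" * 10 + "N" * 10, "blocks")


@pytest.fixture
def alternating_trace():
    return trace_from_string("PN" * 10, "alternating")
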