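import numpy as np
import pytest

from convoturn import build_lists
from convoturn.experiment import SegmentRef
from convoturn.synthetic import ConvGenParams, generate_synthetic_conversation


@pytest.fixture(scope="session")
def small_conversation():
    """A seeded 15-turn synthetic conversation with ground-truth timeline."""
    return generate_synthetic_conversation(ConvGenParams(n_transfers=14), seed=42)


@pytest.fixture(scope="session")
def long_pause_conversation():
    """Conversation seeded with internal pauses of 350-2000 ms in every turn."""
    params = ConvGenParams(
        n_transfers=14, internal_pause_prob=1.0, internal_pause_range_ms=(350.0, 2000.0)
    )
    return generate_synthetic_conversation(params, seed=7)


@pytest.fixture(scope="session")
def segment_inventory():
    """The default 4 pairs x 8 segments stimulus inventory."""
    rng = np.random.default_rng(11)
    return [
        SegmentRef(
            pair_id=p,
            segment_idx=s,
            duration_s=float(rng.uniform(29.0, 36.9)),
            n_transfers=int(rng.integers(12, 26)),
        )
        for p in range(1, 5)
        for s in range(1, 9)
    ]


@pytest.fixture(scope="session")
def presentation_lists(segment_inventory):
    return build_lists(segment_inventory, n_lists=10, master_seed=5)
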