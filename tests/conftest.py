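import numpy as np
import pytest

from crowtag.formats_io import CLASSES, EventBox, SelectionTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_selection_table(rng, n, file_id="f0", labels=CLASSES):
    """Non-degenerate random table of n boxes (possibly overlapping)."""
    rows = []
    for _ in range(n):
        start = float(rng.uniform(0.0, 50.0))
        dur = float(rng.uniform(0.05, 2.0))
        rows.append(
            EventBox(start, start + dur, str(rng.choice(labels)),
                     file_id=file_id)
        )
    return SelectionTable(rows)


@pytest.fixture
def toy_boxes():
    return SelectionTable(
        [
            EventBox(0.0, 1.0, "Focal", file_id="f0"),
            EventBox(2.0, 2.5, "Cuckoo", file_id="f0"),
            EventBox(4.0, 4.33, "Unknown", file_id="f0"),
        ]
    )
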