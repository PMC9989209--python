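import numpy as np
import pytest

from serosig import MarkerPanel


@pytest.fixture
def tiny_panel() -> MarkerPanel:
    """3 subjects x 2 markers, both arms present."""
    return MarkerPanel(
        subject_ids=["a", "b", "c"],
        labels=np.array([1, 0, 1]),
        marker_ids=["m1", "m2"],
        values=np.array([[1.0, 2.0], [3.0, 0.0], [5.5, 6.25]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
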