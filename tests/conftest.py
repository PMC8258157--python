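import logging

import numpy as np
import pytest

from periograde.types import DetectionSet, FDILabel, ToothInstance


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # the calibration/transfer warnings are expected in stress tests
    logging.getLogger("periograde").setLevel(logging.ERROR)
    yield


def rect_tooth(iid, x, y, w=20.0, h=40.0, label=None, score=1.0):
    contour = [
        (x - w / 2, y - h / 2),
        (x + w / 2, y - h / 2),
        (x + w / 2, y + h / 2),
        (x - w / 2, y + h / 2),
    ]
    return ToothInstance(
        iid, contour, score=score, label=FDILabel(label) if label else None
    )


@pytest.fixture
def rect_tooth_factory():
    return rect_tooth


@pytest.fixture
def two_row_scene():
    """16 upper centers at y=100 and 16 lower at y=300, uniform x spacing."""
    teeth = [rect_tooth(f"u{i}", 100 + 50 * i, 100) for i in range(16)]
    teeth += [rect_tooth(f"l{i}", 100 + 50 * i, 300) for i in range(16)]
    return DetectionSet("two_rows", (1024, 512), teeth, "binary")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
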