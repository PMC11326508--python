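import numpy as np
import pytest

from spinedet.annotations import SpineAnnotation
from spinedet.label_codec import CodecConfig
from spinedet.synthetic_spine import SpineSimParams, generate_case


@pytest.fixture(scope="session")
def default_case():
    """One representative simulated case at full (1024x512) scale."""
    return generate_case(SpineSimParams(seed=1), render=False)


@pytest.fixture(scope="session")
def default_codec():
    return CodecConfig()


@pytest.fixture(scope="session")
def straight_annotation():
    """17 congruent axis-aligned rectangles stacked vertically."""
    return make_straight_annotation()


def make_straight_annotation(width=80.0, height=40.0, spacing=55.0):
    corners = np.empty((17, 4, 2))
    cx = 256.0
    for i in range(17):
        cy = 80.0 + i * spacing
        corners[i] = [
            [cx - width / 2, cy - height / 2],
            [cx + width / 2, cy - height / 2],
            [cx - width / 2, cy + height / 2],
            [cx + width / 2, cy + height / 2],
        ]
    return SpineAnnotation.from_corner_array(corners, 1024, 512)


def make_tilted_annotation(tilts_deg, width=80.0, height=40.0, spacing=55.0):
    """Rectangles with prescribed tilts on a straight vertical axis."""
    corners = np.empty((len(tilts_deg), 4, 2))
    cx = 256.0
    for i, tilt in enumerate(tilts_deg):
        cy = 80.0 + i * spacing
        t = np.radians(tilt)
        ax = np.array([np.cos(t), np.sin(t)])        # left->right axis
        dn = np.array([-np.sin(t), np.cos(t)])       # top->bottom axis
        c = np.array([cx, cy])
        corners[i, 0] = c - width / 2 * ax - height / 2 * dn
        corners[i, 1] = c + width / 2 * ax - height / 2 * dn
        corners[i, 2] = c - width / 2 * ax + height / 2 * dn
        corners[i, 3] = c + width / 2 * ax + height / 2 * dn
    return SpineAnnotation.from_corner_array(corners, 1024, 512)
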