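import math

import numpy as np
import pytest

from fishscore.image_io import split_channels
from fishscore.nuclei import NucleusLabelMap, segment_nuclei
from fishscore.synthetic import SyntheticSpec, generate_case


@pytest.fixture(scope="session")
def default_case():
    """One rendered default case (20 nuclei, 4 red + 2 green, noise 0.02)."""
    spec = SyntheticSpec(seed=42)
    img, truth = generate_case(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def default_channels(default_case):
    _, img, _ = default_case
    return split_channels(img)


@pytest.fixture(scope="session")
def default_nuclei(default_channels) -> NucleusLabelMap:
    return segment_nuclei(default_channels[2])


def label_for(truth_nucleus, nmap: NucleusLabelMap) -> int:
    """Label id of the segmented nucleus nearest a ground-truth center."""
    best = min(
        nmap.features,
        key=lambda f: math.hypot(
            truth_nucleus.center[0] - f.centroid[0],
            truth_nucleus.center[1] - f.centroid[1],
        ),
    )
    return best.label_id


def draw_disc(canvas: np.ndarray, center: tuple[int, int], radius: float, value: float) -> np.ndarray:
    rr, cc = np.indices(canvas.shape)
    inside = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
    canvas[inside] = value
    return canvas


def disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
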