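import logging

import numpy as np
import pytest

from mtcortex import ImageGrid, PolyPath
from mtcortex import synthetic as sy


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # skipped-profile warnings are expected on border junctions
    logging.getLogger("mtcortex").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def straight_path():
    """Horizontal junction at y = 10 µm across a 20 µm field."""
    return PolyPath([[1.0, 10.0], [19.0, 10.0]], kind="junction", path_id="j0")


@pytest.fixture(scope="session")
def ridge_image(straight_path):
    """Noise-free Gaussian ridge (sigma 0.3 µm, amplitude 100, background 0)."""
    return sy.render_junction_scene([straight_path], profile_sigma=0.3,
                                    amplitude=100.0, background=0.0,
                                    noise_sd=0.0, field=(20.0, 20.0),
                                    pixel_size=0.1, seed=0)


@pytest.fixture(scope="session")
def mosaic25():
    return sy.make_cell_mosaic(25, (50.0, 50.0), seed=7)


def stripe_image(theta_deg: float, n: int = 200, pixel_size: float = 0.1,
                 wavelength: float = 1.0) -> ImageGrid:
    """Sinusoidal stripes whose fibril axis runs at ``theta_deg``."""
    xs = (np.arange(n) + 0.5) * pixel_size
    X, Y = np.meshgrid(xs, xs)
    t = np.radians(theta_deg)
    vals = 50.0 + 40.0 * np.sin(2 * np.pi / wavelength * (-X * np.sin(t) + Y * np.cos(t)))
    return ImageGrid(np.clip(vals, 0.0, None), pixel_size)


def match_detections(truth, detections, tol: float = 0.3):
    """Greedy nearest matching of detections to ground truth within ``tol``."""
    used = set()
    tp = 0
    for d in detections:
        best, bd = None, np.inf
        for i, c in enumerate(truth):
            if i in used:
                continue
            dd = np.hypot(d.x - c.x, d.y - c.y)
            if dd < bd:
                bd, best = dd, i
        if bd <= tol:
            tp += 1
            used.add(best)
    precision = tp / len(detections) if detections else float("nan")
    recall = tp / len(truth) if truth else float("nan")
    return precision, recall
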