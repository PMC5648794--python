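import numpy as np
import pytest

from histomorph import NucleiSet, NucleusBoundary


def make_ellipse(cx, cy, a, b, angle_deg=0.0, n=64):
    """Vertices of a discretised ellipse (counter-clockwise, open ring)."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    theta = np.radians(angle_deg)
    x = a * np.cos(t)
    y = b * np.sin(t)
    xr = cx + x * np.cos(theta) - y * np.sin(theta)
    yr = cy + x * np.sin(theta) + y * np.cos(theta)
    return np.column_stack([xr, yr])


def make_circle(cx, cy, r, n=64):
    return make_ellipse(cx, cy, r, r, n=n)


def nuclei_from_polygons(polys, image_size=(512, 512), spot_id="test", centroids=None):
    """NucleiSet from raw vertex arrays; optional exact centroids (must agree
    with the polygon area-centroid within the 1e-6 px invariant)."""
    nuclei = [
        NucleusBoundary(
            nucleus_id=f"n{i:04d}",
            vertices=v,
            centroid=None if centroids is None else np.asarray(centroids[i], float),
        )
        for i, v in enumerate(polys)
    ]
    return NucleiSet(spot_id=spot_id, nuclei=nuclei, image_size=image_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def three_circles():
    return nuclei_from_polygons([
        make_circle(100, 100, 20),
        make_circle(200, 150, 15),
        make_circle(150, 250, 25),
    ])
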