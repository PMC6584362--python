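import numpy as np
import pytest

from ovimorph import CellPolygon, PlateSpec, TissuePlate, generate_hex_plate


@pytest.fixture(scope="session")
def unit_square():
    return CellPolygon(1, np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]))


@pytest.fixture(scope="session")
def grid_plate():
    """Perfect 10 x 5 grid of unit squares (10 per row, 5 per column)."""
    cells = []
    cid = 1
    for j in range(5):
        for i in range(10):
            cells.append(CellPolygon(cid, np.array(
                [[i, j], [i + 1, j], [i + 1, j + 1], [i, j + 1]], dtype=float)))
            cid += 1
    return TissuePlate(cells=tuple(cells))


@pytest.fixture(scope="session")
def small_hex_plate():
    """Noise-free 12 x 10 tessellation, s = 1.5, half the rows PD-aligned."""
    return generate_hex_plate(
        PlateSpec(12, 10, cell_area=4.0, shape_ratio=1.5,
                  aligned_fraction=0.5, orientation_noise=0.0, seed=7)
    )


def random_convex_polygon(rng, n_points=12, aspect=2.0):
    """Convex hull of random points, anisotropically stretched."""
    from scipy.spatial import ConvexHull

    pts = rng.standard_normal((n_points, 2)) * [aspect, 1.0] + 3.0
    hull = ConvexHull(pts)
    return pts[hull.vertices]
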