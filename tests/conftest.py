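import math

import numpy as np
import pytest

from cinescar import PhantomConfig, generate_loop


def small_config(**overrides) -> PhantomConfig:
    """A compact noise-free phantom used across tests (fast to render)."""
    base = dict(
        grid_size=64,
        n_frames=16,
        center=(32.0, 32.0),
        r_endo_ed=12.0,
        wall_thickness_ed=6.0,
        contraction_fraction=0.25,
        scar_present=False,
        scar_sector=(0.0, math.pi / 2),
        scar_motion_ratio=0.0,
        noise_sigma=0.0,
        seed=0,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def normal_phantom():
    return generate_loop(small_config())


@pytest.fixture(scope="session")
def scar_phantom():
    """kappa = 0.1: the sector contracts at 10% of normal excursion."""
    return generate_loop(small_config(scar_present=True, scar_motion_ratio=0.1))


def brute_force_point_in_polygon(polygon: np.ndarray, x: float, y: float) -> bool:
    """Scalar even-odd ray-casting oracle, written independently of the
    vectorised rasterizer (loops over edges, casts the ray to +x)."""
    inside = False
    n = len(polygon)
    for i in range(n):
        x1, y1 = polygon[i]
        x2, y2 = polygon[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
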