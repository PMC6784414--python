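"""Shared fixtures: synthetic limbs, random rigid transforms, oracles."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from stiflemetrics import measure_limb
from stiflemetrics.synthetic import SyntheticLimbSpec, generate_limb


@pytest.fixture(scope="session")
def default_limb():
    """The median-profile synthetic limb (deterministic)."""
    return generate_limb(SyntheticLimbSpec())


@pytest.fixture(scope="session")
def default_measurement(default_limb):
    metrics, details = measure_limb(
        default_limb.landmarks, default_limb.tibia, default_limb.mask
    )
    return metrics, details


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_rigid(rng):
    """A random rotation matrix and translation vector."""
    r = Rotation.random(random_state=np.random.RandomState(rng.integers(2**31)))
    t = rng.uniform(-100.0, 100.0, size=3)
    return r.as_matrix(), t


def grid_min_line_distance(l1, l2, half_width=300.0, n=41, max_iter=120):
    """Brute-force minimum of |P(s) - Q(t)| over a refined parameter grid.

    Independent oracle for the common-perpendicular distance: dense grid
    over both line parameters, expanding the search window whenever the
    minimum lands on its boundary (near-parallel lines put the feet of
    the common perpendicular arbitrarily far out) and contracting around
    interior minima until the grid step is negligible.
    """
    s0 = t0 = 0.0
    w = half_width
    best = np.inf
    for _ in range(max_iter):
        s = s0 + np.linspace(-w, w, n)
        t = t0 + np.linspace(-w, w, n)
        p = l1.point[None, :] + s[:, None] * l1.direction[None, :]
        q = l2.point[None, :] + t[:, None] * l2.direction[None, :]
        d2 = ((p[:, None, :] - q[None, :, :]) ** 2).sum(axis=2)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        best = float(np.sqrt(d2[i, j]))
        s0, t0 = float(s[i]), float(t[j])
        if i in (0, n - 1) or j in (0, n - 1):
            w *= 4.0  # chase a minimum outside the window
        else:
            if w < 1e-4:
                break
            w = 4.0 * w / (n - 1)
    return best


def triangle_vertex_angle(a, b, c):
    """Coordinate-construction oracle for the angle opposite side c.

    Builds the triangle explicitly by circle intersection (sides a and b
    from the origin, closing side c) and measures the vertex angle with a
    normalized dot product.
    """
    p = np.array([a, 0.0])
    qx = (a * a + b * b - c * c) / (2.0 * a)
    qy = np.sqrt(max(b * b - qx * qx, 0.0))
    q = np.array([qx, qy])
    cos = float(p @ q) / (np.linalg.norm(p) * np.linalg.norm(q))
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
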