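"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from woundhalve.geometry import BinaryMask


def random_blob_mask(rng: np.random.Generator, size: int = 48) -> BinaryMask:
    """Union of a few random disks: a compact, irregular test mask."""
    g = np.zeros((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    for _ in range(int(rng.integers(2, 6))):
        cx, cy = rng.uniform(size * 0.25, size * 0.75, size=2)
        r = rng.uniform(size * 0.08, size * 0.22)
        g |= (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 < r**2
    if g.sum() < 3:  # pragma: no cover - disks above cannot all miss
        g[size // 2 - 2 : size // 2 + 2, size // 2 - 2 : size // 2 + 2] = True
    return BinaryMask(g)


def brute_force_min_box_extents(points: np.ndarray, step_deg: float = 0.05):
    """Exhaustive orientation-grid search for the minimum-area box.

    Independent of the rotating-calipers implementation: scans orientations
    on a uniform grid and measures the center-extent product.
    """
    pts = np.asarray(points, float)
    if len(pts) >= 3:
        pts = pts[ConvexHull(pts).vertices]
    ang = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    c, s = np.cos(ang), np.sin(ang)
    X = pts @ np.vstack([c, s])  # (h, m) projections on the rotated x axis
    Y = pts @ np.vstack([-s, c])
    areas = np.ptp(X, axis=0) * np.ptp(Y, axis=0)
    return float(areas.min())


def point_in_polygon_oracle(x: float, y: float, vertices, eps: float = 1e-9):
    """Even-odd crossing-number test; ``None`` for boundary-ambiguous points."""
    v = np.asarray(vertices, float)
    n = len(v)
    p = np.array([x, y])
    for i in range(n):
        a, b = v[i], v[(i + 1) % n]
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((p - a) @ ab / denom, 0.0, 1.0) if denom > 0 else 0.0
        if np.linalg.norm(p - (a + t * ab)) < eps:
            return None
    inside = False
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if xint > x:
                inside = not inside
    return inside


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240620)
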