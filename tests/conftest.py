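"""Shared fixtures: programmatic image and scenario builders."""

from __future__ import annotations

import numpy as np
import pytest


def make_blob_frame(
    n_blobs: int,
    rng: np.random.Generator,
    size: int = 160,
    with_bar: bool = True,
    with_holes: bool = True,
    with_salt: bool = True,
    radius: float = 4.5,
) -> np.ndarray:
    """Grayscale frame with ``n_blobs`` bright disks on a 3-column grid,
    optional single-pixel holes, isolated salt noise, and one thin bar of
    bounding-box aspect ratio 15 (removed by the shape constraint)."""
    img = np.full((size, size), 10.0)
    yy, xx = np.mgrid[0:size, 0:size]
    centers = []
    for i in range(n_blobs):
        cx, cy = 20 + 60 * (i % 3), 30 + 60 * (i // 3)
        disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
        img[disk] = 200.0
        if with_holes:
            img[cy, cx] = 10.0
            img[cy, cx - 1] = 10.0
        centers.append((cx, cy))
    if with_salt:
        for _ in range(15):
            x, y = rng.integers(5, size - 5, 2)
            if all((x - cx) ** 2 + (y - cy) ** 2 > 15**2 for cx, cy in centers):
                img[y, x] = 220.0
    if with_bar:
        img[size - 12 : size - 10, 20:50] = 200.0  # 2x30 bar
    return img


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
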