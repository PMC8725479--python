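from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from lungrad.preprocess import DiscretizedROI


def _roi(levels, mask=None) -> DiscretizedROI:
    levels = np.asarray(levels, dtype=np.int64)
    if mask is None:
        mask = np.ones_like(levels, dtype=bool)
    return DiscretizedROI(levels=levels, mask=np.asarray(mask, dtype=bool))


@pytest.fixture
def make_roi():
    return _roi


def small_fixture_set() -> list[DiscretizedROI]:
    """Exhaustive-oracle fixture set: deterministic + seeded random <= 8x8."""
    rois = []
    # checkerboard 4x4 of {0,1}
    cb = np.indices((4, 4)).sum(axis=0) % 2
    rois.append(_roi(cb))
    # horizontal stripes of {0, 255}
    stripes = np.zeros((6, 6), dtype=int)
    stripes[::2] = 255
    rois.append(_roi(stripes))
    # constant-ish with one bright pixel
    spot = np.zeros((5, 5), dtype=int)
    spot[2, 2] = 200
    rois.append(_roi(spot))
    # random levels, random masks
    rng = np.random.default_rng(12345)
    for _ in range(12):
        shape = tuple(rng.integers(3, 9, size=2))
        levels = rng.integers(0, 256, size=shape)
        mask = rng.random(shape) < 0.75
        if mask.sum() < 4:
            mask[:2, :2] = True
        rois.append(_roi(levels, mask))
    # few grey levels (many ties/zones)
    for _ in range(6):
        shape = tuple(rng.integers(4, 9, size=2))
        levels = rng.integers(0, 4, size=shape)
        mask = rng.random(shape) < 0.85
        if mask.sum() < 4:
            mask[:2, :2] = True
        rois.append(_roi(levels, mask))
    return rois


@pytest.fixture(scope="session")
def fixture_rois():
    return small_fixture_set()
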