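"""Texture count matrices: GLCM, GLRLM, GLSZM, NGTDM.

All four are computed on a :class:`~lungrad.preprocess.DiscretizedROI`
(256 grey levels) and only inside the mask: co-occurrence pairs need both
pixels in-mask, runs and zones break at mask boundaries, and neighbourhood
averages use in-mask neighbours only.  Integer counts are kept exact so they
can be compared bit-for-bit against brute-force enumerations.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from ..preprocess import N_LEVELS, DiscretizedROI

# direction -> (row offset, col offset); 0 deg is along a row, angles CCW
DIRECTIONS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
DEFAULT_ANGLES = (0, 45, 90, 135)

_SENTINEL = -1


class DegenerateROIError(ValueError):
    """ROI too degenerate for the requested texture matrix."""


@dataclasses.dataclass
class GLCM:
    """Grey-level co-occurrence counts (256x256), optionally normalized."""

    matrix: np.ndarray
    state: str  # "counts" | "normalized"
    aggregation: tuple  # ((angle, distance), ...)

    def normalized(self) -> "GLCM":
        if self.state == "normalized":
            return self
        total = self.matrix.sum()
        if total == 0:
            raise DegenerateROIError("GLCM has no valid pixel pairs")
        return GLCM(self.matrix / total, "normalized", self.aggregation)


@dataclasses.dataclass
class GLRLM:
    matrix: np.ndarray  # 256 x max run length, counts; column j-1 = length j
    angles: tuple

    @property
    def n_runs(self) -> int:
        return int(self.matrix.sum())


@dataclasses.dataclass
class GLSZM:
    matrix: np.ndarray  # 256 x max zone size, counts; column j-1 = size j
    connectivity: int = 8

    @property
    def n_zones(self) -> int:
        return int(self.matrix.sum())


@dataclasses.dataclass
class NGTDM:
    """Per-level occurrence counts n_i and absolute-difference sums s_i."""

    n: np.ndarray  # (256,) int
    s: np.ndarray  # (256,) float


def compute_glcm(
    roi: DiscretizedROI,
    distance: int = 1,
    angles=DEFAULT_ANGLES,
    symmetric: bool = True,
    merge: bool = True,
):
    """Co-occurrence counts over pixel pairs with both ends in-mask.

    With ``merge=True`` (the default) the per-direction count matrices are
    summed before normalization; with ``merge=False`` a list of per-direction
    GLCMs is returned (used by the directional spread features).
    """
    levels = roi.levels
    mask = roi.mask
    per_direction = []
    for angle in angles:
        dr, dc = DIRECTIONS[angle]
        dr, dc = dr * distance, dc * distance
        rows, cols = levels.shape
        r0 = slice(max(0, -dr), min(rows, rows - dr))
        c0 = slice(max(0, -dc), min(cols, cols - dc))
        r1 = slice(max(0, dr), min(rows, rows + dr))
        c1 = slice(max(0, dc), min(cols, cols + dc))
        valid = mask[r0, c0] & mask[r1, c1]
        a = levels[r0, c0][valid]
        b = levels[r1, c1][valid]
        counts = np.zeros(N_LEVELS * N_LEVELS, dtype=np.int64)
        np.add.at(counts, a * N_LEVELS + b, 1)
        if symmetric:
            np.add.at(counts, b * N_LEVELS + a, 1)
        per_direction.append(
            GLCM(counts.reshape(N_LEVELS, N_LEVELS), "counts", ((angle, distance),))
        )
    if not merge:
        return per_direction
    total = sum(g.matrix for g in per_direction)
    if total.sum() == 0:
        raise DegenerateROIError("no valid pixel pair in any direction")
    return GLCM(total, "counts", tuple((a, distance) for a in angles))


def _lines(levels: np.ndarray, mask: np.ndarray, angle: int) -> list[np.ndarray]:
    """Scan lines of the image along one direction, out-of-mask as sentinel."""
    arr = np.where(mask, levels, _SENTINEL)
    if angle == 0:
        return list(arr)
    if angle == 90:
        return list(arr.T)
    if angle == 135:  # main diagonals
        return [np.diagonal(arr, offset=k) for k in range(-arr.shape[0] + 1, arr.shape[1])]
    if angle == 45:  # anti-diagonals
        f = np.fliplr(arr)
        return [np.diagonal(f, offset=k) for k in range(-f.shape[0] + 1, f.shape[1])]
    raise ValueError(f"unsupported angle {angle}")


def _run_lengths(line: np.ndarray):
    """(level, run length) pairs of maximal constant runs, skipping sentinel."""
    if line.size == 0:
        return
    boundaries = np.flatnonzero(np.diff(line)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [line.size]))
    for s, e in zip(starts, ends):
        if line[s] != _SENTINEL:
            yield int(line[s]), int(e - s)


def compute_glrlm(roi: DiscretizedROI, angles=DEFAULT_ANGLES) -> GLRLM:
    """Run-length counts; runs break at mask boundaries, directions summed."""
    max_len = max(roi.levels.shape) if max(roi.levels.shape) else 1
    matrix = np.zeros((N_LEVELS, max_len), dtype=np.int64)
    for angle in angles:
        for line in _lines(roi.levels, roi.mask, angle):
            for level, length in _run_lengths(np.asarray(line)):
                matrix[level, length - 1] += 1
    if matrix.sum() == 0:
        raise DegenerateROIError("empty mask: no runs")
    last = int(np.flatnonzero(matrix.any(axis=0)).max()) + 1
    return GLRLM(matrix[:, :last], tuple(angles))


def compute_glszm(roi: DiscretizedROI, connectivity: int = 8) -> GLSZM:
    """Size-zone counts: connected components of equal level within the mask."""
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    mask = roi.mask
    n_pixels = int(mask.sum())
    if n_pixels == 0:
        raise DegenerateROIError("empty mask: no zones")
    matrix = np.zeros((N_LEVELS, n_pixels), dtype=np.int64)
    inside = roi.levels[mask]
    for level in np.unique(inside):
        binary = (roi.levels == level) & mask
        labeled, n_comp = ndimage.label(binary, structure=structure)
        if n_comp:
            sizes = np.bincount(labeled.ravel())[1:]
            for size in sizes:
                matrix[level, size - 1] += 1
    last = int(np.flatnonzero(matrix.any(axis=0)).max()) + 1
    return GLSZM(matrix[:, :last], connectivity)


def compute_ngtdm(roi: DiscretizedROI) -> NGTDM:
    """Neighbourhood grey-tone differences (Chebyshev radius 1).

    For each in-mask pixel with >= 1 in-mask neighbour, the absolute
    difference between its level and the mean level of its in-mask
    neighbours is accumulated into ``s`` at the pixel's level.
    """
    mask = roi.mask
    levels = roi.levels.astype(np.float64)
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0.0
    masked_levels = np.where(mask, levels, 0.0)
    neighbour_sum = ndimage.correlate(masked_levels, kernel, mode="constant", cval=0.0)
    neighbour_cnt = ndimage.correlate(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    valid = mask & (neighbour_cnt > 0)
    if not valid.any():
        raise DegenerateROIError("no pixel with an in-mask neighbour")
    diffs = np.abs(levels[valid] - neighbour_sum[valid] / neighbour_cnt[valid])
    lv = roi.levels[valid]
    n = np.bincount(lv, minlength=N_LEVELS).astype(np.int64)
    s = np.bincount(lv, weights=diffs, minlength=N_LEVELS)
    return NGTDM(n=n, s=s)
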