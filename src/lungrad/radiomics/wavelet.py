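"""First-level 2-D Daubechies-5 decomposition of the masked ROI crop.

Self-contained separable DWT (no external wavelet dependency).  The ROI's
bounding-box crop, with out-of-mask pixels filled by the in-mask mean, is
decomposed into four subbands (approximation + horizontal/vertical/diagonal
detail).  Each subband gets a mask obtained by 2x2 OR-decimation of the ROI
mask, aligned to the filter delay, and is re-normalized to 256 levels before
feature extraction.

Boundary handling: ``symmetric`` (default, whole-sample reflection of the
crop) or ``periodization`` (circular; exactly orthonormal, so coefficient
energy equals input energy — used by the energy-conservation checks).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..preprocess import DiscretizedROI, MaskedImage, normalize_roi

# Daubechies-5 (10-tap) orthonormal scaling filter, low-pass decomposition
# order (coefficients sum to sqrt(2), squared norm 1).
DB5_DEC_LO = np.array(
    [
        0.003335725285001549,
        -0.012580751999015526,
        -0.006241490213011705,
        0.07757149384006515,
        -0.03224486958502952,
        -0.24229488706619015,
        0.13842814590110342,
        0.7243085284385744,
        0.6038292697974729,
        0.160102397974125,
    ]
)
# Quadrature mirror: hi[k] = (-1)^k lo[L-1-k]
DB5_DEC_HI = DB5_DEC_LO[::-1].copy()
DB5_DEC_HI[1::2] *= -1.0

SUBBAND_NAMES = ("approx", "horiz", "vert", "diag")
MIN_BBOX = 16


class BoundingBoxTooSmallError(ValueError):
    pass


@dataclasses.dataclass
class SubbandSet:
    """The four subband coefficient grids plus the decimated mask."""

    coeffs: dict[str, np.ndarray]  # name -> 2-D float array (same shape)
    mask: np.ndarray  # decimated boolean mask, same shape as each subband


def _dwt1d(x: np.ndarray, filt: np.ndarray, mode: str) -> np.ndarray:
    """Single-level 1-D analysis: extend, convolve, downsample by 2."""
    L = filt.size
    if mode == "symmetric":
        ext = np.pad(x, (L - 1, L - 1), mode="symmetric")
        full = np.convolve(ext, filt, mode="valid")  # length n + L - 1
        return full[1::2]
    if mode == "periodization":
        n = x.size
        if n % 2:
            x = np.concatenate([x, x[-1:]])
            n += 1
        ext = np.concatenate([x[-(L - 1):], x])
        full = np.convolve(ext, filt, mode="valid")  # circular, length n
        return full[1::2]
    raise ValueError(f"unknown boundary mode {mode!r}")


def _dwt_axis(arr: np.ndarray, filt: np.ndarray, axis: int, mode: str) -> np.ndarray:
    return np.apply_along_axis(_dwt1d, axis, arr, filt, mode)


def dwt2(arr: np.ndarray, mode: str = "symmetric") -> dict[str, np.ndarray]:
    """2-D single-level DWT; returns the four named subbands.

    ``horiz`` is high-pass along rows (axis 0), ``vert`` along columns,
    ``diag`` along both.
    """
    lo0 = _dwt_axis(arr, DB5_DEC_LO, 0, mode)
    hi0 = _dwt_axis(arr, DB5_DEC_HI, 0, mode)
    return {
        "approx": _dwt_axis(lo0, DB5_DEC_LO, 1, mode),
        "vert": _dwt_axis(lo0, DB5_DEC_HI, 1, mode),
        "horiz": _dwt_axis(hi0, DB5_DEC_LO, 1, mode),
        "diag": _dwt_axis(hi0, DB5_DEC_HI, 1, mode),
    }


def _decimate_mask(mask: np.ndarray, out_shape: tuple[int, int], mode: str) -> np.ndarray:
    """2x2 OR-decimation of the mask, embedded at the subband's filter offset."""
    rows, cols = mask.shape
    pad = np.zeros((rows + rows % 2, cols + cols % 2), dtype=bool)
    pad[:rows, :cols] = mask
    dec = pad.reshape(pad.shape[0] // 2, 2, pad.shape[1] // 2, 2).any(axis=(1, 3))
    out = np.zeros(out_shape, dtype=bool)
    if mode == "periodization":
        off_r = off_c = 0
    else:
        # output k draws on input positions around 2k - (L/2 - 1): delay L//4
        off_r = min((DB5_DEC_LO.size - 2) // 4, out_shape[0] - dec.shape[0])
        off_c = min((DB5_DEC_LO.size - 2) // 4, out_shape[1] - dec.shape[1])
    out[off_r : off_r + dec.shape[0], off_c : off_c + dec.shape[1]] = dec[
        : out_shape[0] - off_r, : out_shape[1] - off_c
    ]
    return out


def wavelet_subbands(
    roi: DiscretizedROI,
    mode: str = "symmetric",
    masked: bool = True,
    outlier_sigma: float = 3.0,
) -> dict[str, DiscretizedROI]:
    """Decompose the ROI crop and re-normalize each subband to 256 levels.

    ``masked=False`` uses the full rectangular crop as the subband mask
    (alternative reading of where subband features are evaluated).
    """
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("empty mask")
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    if (r1 - r0) < MIN_BBOX or (c1 - c0) < MIN_BBOX:
        raise BoundingBoxTooSmallError(
            f"mask bounding box {(r1 - r0, c1 - c0)} smaller than {MIN_BBOX}x{MIN_BBOX}"
        )
    crop_mask = roi.mask[r0:r1, c0:c1]
    crop = roi.levels[r0:r1, c0:c1].astype(np.float64)
    fill = crop[crop_mask].mean()
    crop = np.where(crop_mask, crop, fill)

    bands = dwt2(crop, mode=mode)
    out_shape = bands["approx"].shape
    band_mask = (
        _decimate_mask(crop_mask, out_shape, mode)
        if masked
        else np.ones(out_shape, dtype=bool)
    )
    result = {}
    for name in SUBBAND_NAMES:
        img = MaskedImage(pixels=bands[name], mask=band_mask)
        result[name] = normalize_roi(img, outlier_sigma=outlier_sigma, min_roi_pixels=1)
    return result
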