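"""Per-subject feature extraction: 380 named radiomics values per image."""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from typing import Iterable

import numpy as np
import pandas as pd

from ..preprocess import DiscretizedROI, MaskedImage, normalize_roi
from . import features as F
from .matrices import compute_glcm, compute_glrlm, compute_glszm, compute_ngtdm
from .registry import PER_BAND_NAMES, RADIOMICS_NAMES
from .wavelet import wavelet_subbands


@dataclasses.dataclass
class ExtractionConfig:
    outlier_sigma: float = 3.0
    min_roi_pixels: int = 32
    glcm_distance: int = 1
    wavelet_mode: str = "symmetric"
    masked_subbands: bool = True


def band_features(roi: DiscretizedROI, config: ExtractionConfig) -> OrderedDict:
    """The 76 per-band features, or zeros when the band ROI is degenerate."""
    out: OrderedDict[str, float] = OrderedDict()
    if roi.degenerate:
        for name in PER_BAND_NAMES:
            out[name] = 0.0
        # conventions that hold even for a constant band
        out["hist_uniformity"] = 1.0
        out["ngtdm_coarseness"] = F.COARSENESS_CAP
        return out
    n_pixels = int(roi.mask.sum())
    out.update(F.histogram_features(roi))
    out.update(F.roi_texture_features(roi, distance=config.glcm_distance))
    out.update(F.glcm_features(compute_glcm(roi, distance=config.glcm_distance)))
    out.update(F.glrlm_features(compute_glrlm(roi), n_pixels))
    out.update(F.glszm_features(compute_glszm(roi), n_pixels))
    out.update(F.ngtdm_features(compute_ngtdm(roi)))
    return OrderedDict((name, out[name]) for name in PER_BAND_NAMES)


def extract_all_features(
    img: MaskedImage, config: ExtractionConfig | None = None
) -> tuple[OrderedDict, bool]:
    """Extract the full 380-entry radiomics vector from one masked image.

    Returns ``(features, degenerate)``.  A degenerate (constant) ROI yields
    an all-zero vector with the flag set; such subjects are excluded from
    modelling by default.
    """
    config = config or ExtractionConfig()
    roi = normalize_roi(
        img, outlier_sigma=config.outlier_sigma, min_roi_pixels=config.min_roi_pixels
    )
    if roi.degenerate:
        return OrderedDict((name, 0.0) for name in RADIOMICS_NAMES), True

    vector: OrderedDict[str, float] = OrderedDict()
    for name, value in band_features(roi, config).items():
        vector[f"orig_{name}"] = value
    bands = wavelet_subbands(
        roi,
        mode=config.wavelet_mode,
        masked=config.masked_subbands,
        outlier_sigma=config.outlier_sigma,
    )
    for band_name, band_roi in bands.items():
        for name, value in band_features(band_roi, config).items():
            vector[f"{band_name}_{name}"] = value
    assert tuple(vector.keys()) == RADIOMICS_NAMES
    return vector, False


def extract_cohort(
    images: Iterable[tuple[str, MaskedImage]], config: ExtractionConfig | None = None
) -> pd.DataFrame:
    """Extract features for many subjects into a DataFrame.

    Rows indexed by subject id; columns are the 380 radiomics names plus a
    boolean ``degenerate`` column.
    """
    rows = {}
    flags = {}
    for subject_id, img in images:
        vec, degenerate = extract_all_features(img, config)
        rows[subject_id] = vec
        flags[subject_id] = degenerate
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RADIOMICS_NAMES))
    df["degenerate"] = pd.Series(flags)
    df.index.name = "subject_id"
    return df
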