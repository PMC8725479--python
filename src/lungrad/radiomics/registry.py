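"""Single source of truth for feature names and their fixed order.

Per band: 16 histogram + 6 directional-spread + 23 GLCM + 13 GLRLM +
13 GLSZM + 5 NGTDM = 76 features; bands are the original ROI plus the four
first-level wavelet subbands, giving 380 radiomics features.  The two
clinical covariates (GA, GDM) are prepended by the feature-table assembly
stage for a 382-column table.
"""

from __future__ import annotations

from .features import (
    GLCM_NAMES,
    GLRLM_NAMES,
    GLSZM_NAMES,
    HISTOGRAM_NAMES,
    NGTDM_NAMES,
    ROI_TEXTURE_NAMES,
)

BAND_PREFIXES = ("orig", "approx", "horiz", "vert", "diag")

PER_BAND_NAMES: tuple[str, ...] = (
    HISTOGRAM_NAMES + ROI_TEXTURE_NAMES + GLCM_NAMES + GLRLM_NAMES + GLSZM_NAMES + NGTDM_NAMES
)

RADIOMICS_NAMES: tuple[str, ...] = tuple(
    f"{band}_{name}" for band in BAND_PREFIXES for name in PER_BAND_NAMES
)

CLINICAL_NAMES = ("ga", "gdm")
ALL_FEATURE_NAMES = CLINICAL_NAMES + RADIOMICS_NAMES

N_PER_BAND = len(PER_BAND_NAMES)
N_RADIOMICS = len(RADIOMICS_NAMES)
N_WAVELET = N_PER_BAND * 4
N_ALL = len(ALL_FEATURE_NAMES)

assert N_PER_BAND == 76
assert N_RADIOMICS == 380
assert N_ALL == 382


def wavelet_feature_names() -> tuple[str, ...]:
    return tuple(n for n in RADIOMICS_NAMES if not n.startswith("orig_"))
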