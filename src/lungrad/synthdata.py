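"""Synthetic cohort generation.

Builds a cohort of masked speckle images plus clinical covariates with a
controlled class structure: the majority ("normal") class is brighter, finer
grained and more homogeneous than the minority ("NRM") class, gestational
age and a binary comorbidity differ by class, and the class ratio is
imbalanced (default 159:51).  Everything is deterministic under one integer
seed via a documented :class:`numpy.random.SeedSequence` splitting scheme:
child 0 drives labels and covariates, child ``1+i`` drives subject ``i``'s
image and mask.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .preprocess import MaskedImage

NRM = "NRM"
NORMAL = "normal"

_GAMMA_SHAPE = 4.0  # speckle: multiplicative gamma noise, mean 1


class TextureParams(BaseModel):
    """Per-class texture knobs for the speckle image generator."""

    brightness: float = Field(gt=0)
    correlation_length: float = Field(ge=1.0, description="speckle grain size, px")
    heterogeneity_sd: float = Field(ge=0.0)


class ClassParams(BaseModel):
    ga_mean: float
    ga_sd: float = Field(ge=0.0)
    gdm_rate: float = Field(ge=0.0, le=1.0)
    texture: TextureParams


class CohortSpec(BaseModel):
    """Cohort shape plus per-class generative parameters.

    Defaults reproduce the study-like structure: 210 subjects with a 51/159
    minority/majority split, class-conditional gestational age of
    34.37 ± 2.42 vs 36.49 ± 0.85 weeks and comorbidity rates 0.65 vs 0.378,
    and a darker/coarser/more heterogeneous minority texture.
    """

    n_total: int = Field(default=210, gt=1)
    n_minority: int = Field(default=51, gt=0)
    normal: ClassParams = ClassParams(
        ga_mean=36.49,
        ga_sd=0.85,
        gdm_rate=0.378,
        texture=TextureParams(brightness=140.0, correlation_length=1.5, heterogeneity_sd=6.0),
    )
    nrm: ClassParams = ClassParams(
        ga_mean=34.37,
        ga_sd=2.42,
        gdm_rate=0.65,
        texture=TextureParams(brightness=120.0, correlation_length=3.0, heterogeneity_sd=14.0),
    )
    image_size: tuple[int, int] = (128, 128)
    mask_kind: Literal["irregular", "square"] = "irregular"
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if not 0 < self.n_minority < self.n_total:
            raise ValueError("require 0 < n_minority < n_total")
        if self.image_size[0] < 64 or self.image_size[1] < 64:
            raise ValueError("image_size must be at least 64x64")
        return self


@dataclasses.dataclass
class SyntheticSubject:
    subject_id: str
    image: MaskedImage | None
    label: str  # NRM | normal
    ga: float
    gdm: int


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_lung_image(
    texture_params: TextureParams,
    image_size: tuple[int, int],
    seed,
    mask: np.ndarray | None = None,
    mask_kind: str = "irregular",
) -> MaskedImage:
    """Draw one speckle image: gamma noise on a smooth base field.

    The pixel field is ``smooth(brightness * G, sigma=correlation_length) + H``
    where ``G`` is i.i.d. gamma(shape 4, mean 1) speckle and ``H`` is a
    zero-mean low-frequency heterogeneity field with the configured SD.
    Larger correlation length -> coarser grain; larger heterogeneity SD ->
    less homogeneous ROI; the expected ROI mean equals the brightness knob.
    """
    rows, cols = image_size
    if rows <= 0 or cols <= 0:
        raise ValueError(f"image size must be positive, got {image_size}")
    rng = _rng(seed)
    speckle = rng.gamma(shape=_GAMMA_SHAPE, scale=1.0 / _GAMMA_SHAPE, size=(rows, cols))
    field = ndimage.gaussian_filter(
        texture_params.brightness * speckle, sigma=texture_params.correlation_length, mode="nearest"
    )
    if texture_params.heterogeneity_sd > 0:
        base = ndimage.gaussian_filter(
            rng.standard_normal((rows, cols)), sigma=min(rows, cols) / 8.0, mode="nearest"
        )
        sd = base.std()
        if sd > 0:
            field = field + (base - base.mean()) * (texture_params.heterogeneity_sd / sd)
    if mask is None:
        mask = generate_roi_mask(image_size, mask_kind, rng)
    return MaskedImage(pixels=field, mask=mask)


def _star_blob(image_size, rng, area_bounds) -> np.ndarray:
    rows, cols = image_size
    target = rng.uniform(*area_bounds) * rows * cols
    r0 = max(math.sqrt(target / math.pi), 9.5)  # bbox stays >= 16 px wide
    # random star-shaped boundary: r(theta) = r0 * (1 + sum_k a_k cos/sin)
    n_harmonics = 4
    amp = rng.uniform(0.05, 0.18, size=n_harmonics)
    phase = rng.uniform(0, 2 * math.pi, size=n_harmonics)
    margin = r0 * 1.3 + 2
    cy = rng.uniform(margin, rows - margin)
    cx = rng.uniform(margin, cols - margin)
    yy, xx = np.mgrid[0:rows, 0:cols]
    dy, dx = yy - cy, xx - cx
    theta = np.arctan2(dy, dx)
    radius = np.hypot(dy, dx)
    bound = r0 * (
        1.0
        + sum(amp[k] * np.cos((k + 2) * theta + phase[k]) for k in range(n_harmonics))
    )
    return radius <= bound


def generate_roi_mask(
    image_size: tuple[int, int],
    kind: Literal["irregular", "square"],
    seed,
    area_bounds: tuple[float, float] = (0.05, 0.20),
    square_side: int | None = None,
) -> np.ndarray:
    """One connected ROI fully inside the image.

    ``irregular`` draws a smoothed star-shaped blob; ``square`` an
    axis-aligned square.  Default area between 5% and 20% of the image.
    """
    rows, cols = image_size
    lo, hi = area_bounds
    if not 0 < lo <= hi or hi > 1:
        raise ValueError(f"invalid area bounds {area_bounds}")
    rng = _rng(seed)
    if kind == "square":
        if square_side is None:
            frac = rng.uniform(lo, hi)
            square_side = max(1, round(math.sqrt(frac * rows * cols)))
            # keep the ROI compatible with the 16x16 wavelet minimum
            square_side = max(square_side, min(16, rows, cols))
        if square_side > min(rows, cols):
            raise ValueError(
                f"square side {square_side} does not fit image {image_size}"
            )
        r0 = int(rng.integers(0, rows - square_side + 1))
        c0 = int(rng.integers(0, cols - square_side + 1))
        mask = np.zeros((rows, cols), dtype=bool)
        mask[r0 : r0 + square_side, c0 : c0 + square_side] = True
        return mask
    if kind != "irregular":
        raise ValueError(f"unknown mask kind {kind!r}")
    min_area = lo * rows * cols
    if min_area < 8 or math.sqrt(hi * rows * cols / math.pi) * 1.3 + 2 > min(rows, cols) / 2:
        raise ValueError(f"area bounds {area_bounds} infeasible for image {image_size}")
    for _ in range(50):
        mask = _star_blob(image_size, rng, area_bounds)
        area = mask.sum()
        n_components = ndimage.label(mask)[1]
        if n_components == 1 and lo * rows * cols * 0.5 <= area <= hi * rows * cols * 1.5:
            return mask
    raise RuntimeError("failed to draw a feasible ROI blob")  # pragma: no cover


def generate_cohort(spec: CohortSpec, with_images: bool = True) -> list[SyntheticSubject]:
    """Generate the full cohort; exactly ``n_minority`` NRM subjects.

    Labels are assigned first, then each subject's covariates are drawn from
    its class distribution and its image from the class texture parameters.
    ``with_images=False`` skips image synthesis (covariate-only cohorts for
    statistical checks at large n).
    """
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.n_total + 1)
    cov_rng = np.random.default_rng(children[0])

    labels = np.array([NRM] * spec.n_minority + [NORMAL] * (spec.n_total - spec.n_minority))
    cov_rng.shuffle(labels)

    subjects = []
    for i, label in enumerate(labels):
        params = spec.nrm if label == NRM else spec.normal
        ga = float(cov_rng.normal(params.ga_mean, params.ga_sd))
        gdm = int(cov_rng.random() < params.gdm_rate)
        img = None
        if with_images:
            img = generate_lung_image(
                params.texture,
                spec.image_size,
                np.random.default_rng(children[i + 1]),
                mask_kind=spec.mask_kind,
            )
        subjects.append(
            SyntheticSubject(subject_id=f"S{i:04d}", image=img, label=str(label), ga=ga, gdm=gdm)
        )
    return subjects


def stratified_split(
    subjects: Sequence, test_fraction: float, seed, labels: Sequence[str] | None = None
) -> tuple[list, list]:
    """Class-stratified split: per class, ``floor((1-f)·n)`` to train.

    The per-class train count is the floor of the train fraction times the
    class size, with the remainder going to test; for (210 subjects, 51
    minority, f=0.2) this yields the 167/43 with 40/11 minority split.
    """
    if not 0 <= test_fraction <= 1:
        raise ValueError("test_fraction must be in [0,1]")
    if labels is None:
        labels = [s.label for s in subjects]
    labels = np.asarray(labels)
    if len(labels) != len(subjects):
        raise ValueError("labels and subjects length mismatch")
    rng = _rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if test_fraction > 0 and len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members")
        n_train = math.floor((1.0 - test_fraction) * len(idx))
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    train_idx.sort()
    test_idx.sort()
    return [subjects[i] for i in train_idx], [subjects[i] for i in test_idx]


def generate_feature_cohort(
    n_majority: int = 127,
    n_minority: int = 40,
    n_informative: int = 4,
    n_noise: int = 16,
    alias_fraction: float = 0.4,
    shift: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Feature-space cohort with heavy class aliasing, for classifier benchmarks.

    The majority class is standard normal in all dimensions.  A fraction
    ``alias_fraction`` of minority points is drawn from the same cloud
    (aliased, unlearnable); each remaining minority point sits in one of
    ``n_informative`` axis-aligned lobes at distance ``shift``.  Minority
    neighbourhoods therefore span lobes and the majority bulk, so synthetic
    interpolation produces minority-labelled points inside majority
    territory, while the lobes themselves are learnable by shallow trees.
    Returns (X, y) with y=1 for the minority class.
    """
    rng = _rng(seed)
    d = n_informative + n_noise
    X_maj = rng.standard_normal((n_majority, d))
    X_min = rng.standard_normal((n_minority, d))
    aliased = rng.random(n_minority) < alias_fraction
    lobes = rng.integers(0, n_informative, size=n_minority)
    for i in range(n_minority):
        if not aliased[i]:
            X_min[i, lobes[i]] = shift + 0.5 * abs(X_min[i, lobes[i]])
    X = np.vstack([X_maj, X_min])
    y = np.concatenate([np.zeros(n_majority, dtype=int), np.ones(n_minority, dtype=int)])
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


def write_cohort(
    subjects: Sequence[SyntheticSubject],
    out_dir: str | Path,
    dicom: bool = False,
) -> Path:
    """Write PNG images + masks and a CSV manifest; returns the manifest path."""
    import imageio.v3 as iio
    import pandas as pd

    from . import dicomio

    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    records = []
    for s in subjects:
        img8 = np.clip(np.round(s.image.pixels), 0, 255).astype(np.uint8)
        if dicom:
            image_path = out_dir / "images" / f"{s.subject_id}.dcm"
            dicomio.write_dicom(image_path, img8)
        else:
            image_path = out_dir / "images" / f"{s.subject_id}.png"
            iio.imwrite(image_path, img8)
        mask_path = out_dir / "masks" / f"{s.subject_id}.png"
        iio.imwrite(mask_path, (s.image.mask * np.uint8(255)))
        records.append(
            {
                "subject_id": s.subject_id,
                "label": s.label,
                "ga": s.ga,
                "gdm": s.gdm,
                "image_path": str(image_path.relative_to(out_dir)),
                "mask_path": str(mask_path.relative_to(out_dir)),
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame.from_records(records).to_csv(manifest, index=False)
    return manifest
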