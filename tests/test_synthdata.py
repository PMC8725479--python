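import numpy as np
import pytest

from lungrad.preprocess import MaskedImage
from lungrad.synthdata import (
    CohortSpec,
    TextureParams,
    generate_cohort,
    generate_feature_cohort,
    generate_lung_image,
    generate_roi_mask,
    stratified_split,
    write_cohort,
)


def test_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_total=10, n_minority=10)
    with pytest.raises(ValueError):
        CohortSpec(image_size=(32, 32))
    with pytest.raises(ValueError):
        TextureParams(brightness=100, correlation_length=0.5, heterogeneity_sd=1)


def test_image_seeded_determinism():
    params = TextureParams(brightness=120, correlation_length=2, heterogeneity_sd=5)
    a = generate_lung_image(params, (64, 64), seed=7)
    b = generate_lung_image(params, (64, 64), seed=7)
    np.testing.assert_array_equal(a.pixels, b.pixels)
    np.testing.assert_array_equal(a.mask, b.mask)


def test_smoothing_limit():
    # no heterogeneity, huge correlation length: variance collapses,
    # ROI mean stays at the brightness knob
    params = TextureParams(brightness=150, correlation_length=30, heterogeneity_sd=0)
    img = generate_lung_image(params, (128, 128), seed=0)
    vals = img.roi_values()
    assert vals.mean() == pytest.approx(150, rel=0.05)
    assert vals.std() < 5.0
    fine = generate_lung_image(
        TextureParams(brightness=150, correlation_length=1, heterogeneity_sd=0),
        (128, 128),
        seed=0,
    )
    assert fine.roi_values().std() > vals.std()


def test_brightness_monotone_monte_carlo():
    # 50 paired draws: brighter parameter wins in >= 95% of pairs
    bright = TextureParams(brightness=140, correlation_length=2, heterogeneity_sd=6)
    dim = TextureParams(brightness=120, correlation_length=2, heterogeneity_sd=6)
    wins = 0
    for seed in range(50):
        a = generate_lung_image(bright, (64, 64), seed=seed)
        b = generate_lung_image(dim, (64, 64), seed=seed)
        wins += a.roi_values().mean() > b.roi_values().mean()
    assert wins >= 48


def test_autocorrelation_width_increases():
    def acf_width(img):
        v = img.pixels - img.pixels.mean()
        f = np.fft.rfft2(v)
        ac = np.fft.irfft2(f * np.conj(f), s=v.shape)
        row = ac[0] / ac[0, 0]
        below = np.flatnonzero(row[: v.shape[1] // 2] < 0.5)
        return below[0] if below.size else v.shape[1] // 2

    fine = generate_lung_image(
        TextureParams(brightness=130, correlation_length=1, heterogeneity_sd=0), (128, 128), 0
    )
    coarse = generate_lung_image(
        TextureParams(brightness=130, correlation_length=4, heterogeneity_sd=0), (128, 128), 0
    )
    assert acf_width(coarse) > acf_width(fine)


def test_square_mask_exact_area():
    mask = generate_roi_mask((256, 256), "square", seed=0, square_side=40)
    assert mask.sum() == 1600


def test_irregular_mask_connected():
    from scipy import ndimage

    for seed in range(5):
        mask = generate_roi_mask((128, 128), "irregular", seed=seed)
        assert ndimage.label(mask)[1] == 1
        assert not mask[0].any() and not mask[-1].any()  # fully inside


def test_mask_bounds_infeasible():
    with pytest.raises(ValueError):
        generate_roi_mask((64, 64), "square", seed=0, square_side=100)


def test_both_mask_kinds_same_feature_schema():
    from lungrad.radiomics import extract_all_features

    params = TextureParams(brightness=130, correlation_length=2, heterogeneity_sd=5)
    img = generate_lung_image(params, (96, 96), seed=1, mask_kind="irregular")
    square = generate_roi_mask((96, 96), "square", seed=2)
    v1, _ = extract_all_features(img)
    v2, _ = extract_all_features(MaskedImage(img.pixels, square))
    assert list(v1.keys()) == list(v2.keys())
    assert len(v1) == 380


def test_cohort_counts_and_determinism():
    spec = CohortSpec(seed=5, image_size=(64, 64), n_total=20, n_minority=6)
    a = generate_cohort(spec)
    b = generate_cohort(spec)
    assert sum(s.label == "NRM" for s in a) == 6
    assert len(a) == 20
    np.testing.assert_array_equal(a[0].image.pixels, b[0].image.pixels)
    assert [s.ga for s in a] == [s.ga for s in b]


def test_cohort_covariate_moments():
    spec = CohortSpec(n_total=20000, n_minority=10000, seed=0)
    subs = generate_cohort(spec, with_images=False)
    ga_nrm = np.array([s.ga for s in subs if s.label == "NRM"])
    ga_norm = np.array([s.ga for s in subs if s.label == "normal"])
    gdm_nrm = np.array([s.gdm for s in subs if s.label == "NRM"])
    # 3-SE tolerances at n = 1e4 per class
    assert abs(ga_nrm.mean() - 34.37) < 3 * 2.42 / 100
    assert abs(ga_norm.mean() - 36.49) < 3 * 0.85 / 100
    assert abs(gdm_nrm.mean() - 0.65) < 0.015


def test_split_matches_published_counts():
    spec = CohortSpec(seed=0)
    subs = generate_cohort(spec, with_images=False)
    train, test = stratified_split(subs, 0.2, seed=0)
    assert len(train) == 167 and len(test) == 43
    assert sum(s.label == "NRM" for s in train) == 40
    assert sum(s.label == "NRM" for s in test) == 11
    ids = {s.subject_id for s in subs}
    assert {s.subject_id for s in train} | {s.subject_id for s in test} == ids
    assert not ({s.subject_id for s in train} & {s.subject_id for s in test})


def test_split_zero_fraction_and_determinism():
    subs = generate_cohort(CohortSpec(n_total=20, n_minority=6, seed=1), with_images=False)
    train, test = stratified_split(subs, 0.0, seed=3)
    assert test == [] and len(train) == 20
    t1, e1 = stratified_split(subs, 0.25, seed=9)
    t2, e2 = stratified_split(subs, 0.25, seed=9)
    assert [s.subject_id for s in t1] == [s.subject_id for s in t2]
    assert [s.subject_id for s in e1] == [s.subject_id for s in e2]


def test_split_empty_class_error():
    subs = generate_cohort(CohortSpec(n_total=20, n_minority=1, seed=1), with_images=False)
    with pytest.raises(ValueError):
        stratified_split(subs, 0.2, seed=0)


def test_downstream_separability_floor():
    """Depth-2 tree on the generative covariates reaches bACC > 0.7."""
    from sklearn.tree import DecisionTreeClassifier

    from lungrad.evaluate import ConfusionCounts, metrics

    baccs = []
    for seed in range(10):
        subs = generate_cohort(
            CohortSpec(n_total=210, n_minority=51, seed=seed), with_images=False
        )
        train, test = stratified_split(subs, 0.2, seed=seed)

        def xy(part):
            X = np.array([[s.ga, s.gdm] for s in part])
            y = np.array([s.label == "NRM" for s in part], dtype=int)
            return X, y

        Xtr, ytr = xy(train)
        Xte, yte = xy(test)
        tree = DecisionTreeClassifier(max_depth=2, random_state=0).fit(Xtr, ytr)
        rep = metrics(ConfusionCounts.from_labels(yte, tree.predict(Xte)))
        baccs.append(rep.bACC)
    assert np.mean(baccs) > 0.7


def test_feature_cohort_shapes():
    X, y = generate_feature_cohort(seed=0)
    assert X.shape == (167, 20)
    assert y.sum() == 40
    X2, y2 = generate_feature_cohort(seed=0)
    np.testing.assert_array_equal(X, X2)


def test_write_cohort_roundtrip(tmp_path):
    import pandas as pd

    from lungrad.preprocess import read_image_and_mask

    subs = generate_cohort(CohortSpec(n_total=4, n_minority=2, seed=2, image_size=(64, 64)))
    manifest = write_cohort(subs, tmp_path)
    df = pd.read_csv(manifest)
    assert len(df) == 4
    rec = df.iloc[0]
    img = read_image_and_mask(tmp_path / rec.image_path, tmp_path / rec.mask_path)
    np.testing.assert_array_equal(img.mask, subs[0].image.mask)
    assert np.abs(img.pixels - np.clip(subs[0].image.pixels, 0, 255)).max() <= 0.5


def test_write_cohort_dicom(tmp_path):
    subs = generate_cohort(CohortSpec(n_total=2, n_minority=1, seed=2, image_size=(64, 64)))
    manifest = write_cohort(subs, tmp_path, dicom=True)
    import pandas as pd

    rec = pd.read_csv(manifest).iloc[0]
    assert rec.image_path.endswith(".dcm")
    from lungrad.preprocess import read_image_and_mask

    img = read_image_and_mask(tmp_path / rec.image_path, tmp_path / rec.mask_path)
    assert img.pixels.shape == (64, 64)
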