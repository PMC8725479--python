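"""Feature formulas on the texture matrices and the level histogram.

Conventions (documented once, used consistently):

* Logarithms are base 2 (entropies in bits).
* Skewness/kurtosis are the Fisher (excess) population versions; both are 0
  when the variance is 0.
* Grey-level weights in GLCM/GLRLM/GLSZM/NGTDM formulas use 1-based level
  indices ``i = level + 1`` so level 0 carries weight 1 (the usual bin-number
  convention; avoids division by zero in low-grey-level emphases).
* Correlation-type features return 0 when a marginal variance is 0.
* NGTDM coarseness is capped at ``COARSENESS_CAP`` when the denominator
  vanishes (constant ROI).
"""

from __future__ import annotations

import numpy as np

from ..preprocess import N_LEVELS, DiscretizedROI
from .matrices import GLCM, GLRLM, GLSZM, NGTDM, compute_glcm

COARSENESS_CAP = 1.0e6

HISTOGRAM_NAMES = (
    "hist_energy",
    "hist_entropy",
    "hist_kurtosis",
    "hist_mean",
    "hist_median_absolute_deviation",
    "hist_median",
    "hist_range",
    "hist_uniformity",
    "hist_variance",
    "hist_root_mean_square",
    "hist_skewness",
    "hist_deviation",
    "hist_histogram_kurtosis",
    "hist_histogram_mean",
    "hist_histogram_variance",
    "hist_histogram_skewness",
)

ROI_TEXTURE_NAMES = (
    "roitex_contrast_mean",
    "roitex_contrast_sd",
    "roitex_covariance_mean",
    "roitex_covariance_sd",
    "roitex_nonsimilarity_mean",
    "roitex_nonsimilarity_sd",
)

GLCM_NAMES = (
    "glcm_energy",
    "glcm_entropy",
    "glcm_dissimilarity",
    "glcm_contrast",
    "glcm_inversed_difference",
    "glcm_correlation1",
    "glcm_correlation2",
    "glcm_homogeneity",
    "glcm_autocorrelation",
    "glcm_cluster_shade",
    "glcm_cluster_prominence",
    "glcm_maximum_probability",
    "glcm_sum_of_squares",
    "glcm_sum_average",
    "glcm_sum_variance",
    "glcm_sum_entropy",
    "glcm_difference_variance",
    "glcm_difference_entropy",
    "glcm_imc1",
    "glcm_imc2",
    "glcm_maximal_correlation_coefficient",
    "glcm_inverse_difference_normalized",
    "glcm_inverse_difference_moment_normalized",
)

GLRLM_NAMES = (
    "glrlm_short_run_emphasis",
    "glrlm_long_run_emphasis",
    "glrlm_grey_level_nonuniformity",
    "glrlm_run_length_nonuniformity",
    "glrlm_run_percentage",
    "glrlm_low_grey_level_run_emphasis",
    "glrlm_high_grey_level_run_emphasis",
    "glrlm_short_run_low_grey_level_emphasis",
    "glrlm_short_run_high_grey_level_emphasis",
    "glrlm_long_run_low_grey_level_emphasis",
    "glrlm_long_run_high_grey_level_emphasis",
    "glrlm_grey_level_variance",
    "glrlm_run_length_variance",
)

GLSZM_NAMES = (
    "glszm_small_zone_emphasis",
    "glszm_large_zone_emphasis",
    "glszm_grey_level_nonuniformity",
    "glszm_zone_size_nonuniformity",
    "glszm_zone_percentage",
    "glszm_low_grey_level_zone_emphasis",
    "glszm_high_grey_level_zone_emphasis",
    "glszm_small_zone_low_grey_level_emphasis",
    "glszm_small_zone_high_grey_level_emphasis",
    "glszm_large_zone_low_grey_level_emphasis",
    "glszm_large_zone_high_grey_level_emphasis",
    "glszm_grey_level_variance",
    "glszm_zone_size_variance",
)

NGTDM_NAMES = (
    "ngtdm_coarseness",
    "ngtdm_contrast",
    "ngtdm_busyness",
    "ngtdm_complexity",
    "ngtdm_strength",
)


def _log2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=np.float64)
    nz = p > 0
    out[nz] = np.log2(p[nz])
    return out


def _moments(values: np.ndarray, probs: np.ndarray):
    mu = float((values * probs).sum())
    var = float(((values - mu) ** 2 * probs).sum())
    if var > 0:
        sd = np.sqrt(var)
        skew = float(((values - mu) ** 3 * probs).sum()) / sd**3
        kurt = float(((values - mu) ** 4 * probs).sum()) / var**2 - 3.0
    else:
        skew, kurt = 0.0, 0.0
    return mu, var, skew, kurt


def histogram_features(roi: DiscretizedROI) -> dict[str, float]:
    """The 16 first-order features of the in-mask level distribution."""
    x = roi.roi_levels().astype(np.float64)
    n = x.size
    counts = np.bincount(roi.roi_levels(), minlength=N_LEVELS)
    p = counts / n
    bins = np.arange(N_LEVELS, dtype=np.float64)
    mu, var, skew, kurt = _moments(bins, p)
    median = float(np.median(x))
    hm, hv, hs, hk = _moments(bins, p)  # histogram-domain moments (bin values)
    return {
        "hist_energy": float((x**2).sum()),
        "hist_entropy": float(-(p * _log2(p)).sum()),
        "hist_kurtosis": kurt,
        "hist_mean": float(x.mean()),
        "hist_median_absolute_deviation": float(np.abs(x - median).mean()),
        "hist_median": median,
        "hist_range": float(x.max() - x.min()),
        "hist_uniformity": float((p**2).sum()),
        "hist_variance": var,
        "hist_root_mean_square": float(np.sqrt((x**2).mean())),
        "hist_skewness": skew,
        "hist_deviation": float(np.sqrt(var)),
        "hist_histogram_kurtosis": hk,
        "hist_histogram_mean": hm,
        "hist_histogram_variance": hv,
        "hist_histogram_skewness": hs,
    }


def _glcm_support(p: np.ndarray):
    present = np.flatnonzero(p.sum(axis=0) + p.sum(axis=1) > 0)
    return p[np.ix_(present, present)], present


def glcm_features(glcm: GLCM) -> dict[str, float]:
    """The 23 co-occurrence features on a normalized, merged GLCM."""
    p_full = glcm.normalized().matrix
    p, present = _glcm_support(p_full)
    idx = (present + 1).astype(np.float64)  # 1-based grey-level weights
    i = idx[:, None]
    j = idx[None, :]
    ng = present.size

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    var_x = float(((idx - mu_x) ** 2 * px).sum())
    var_y = float(((idx - mu_y) ** 2 * py).sum())
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)

    diff = np.abs(i - j)
    # distributions of i+j and |i-j| over 1-based weights
    sum_idx = (i + j).astype(np.int64)
    p_sum = np.bincount(sum_idx.ravel(), weights=p.ravel(), minlength=2 * N_LEVELS + 1)
    k_sum = np.arange(p_sum.size, dtype=np.float64)
    p_diff = np.bincount(
        diff.astype(np.int64).ravel(), weights=p.ravel(), minlength=N_LEVELS
    )
    k_diff = np.arange(p_diff.size, dtype=np.float64)

    entropy = float(-(p * _log2(p)).sum())
    sum_avg = float((k_sum * p_sum).sum())
    diff_avg = float((k_diff * p_diff).sum())

    if sd_x > 0 and sd_y > 0:
        corr1 = (float((i * j * p).sum()) - mu_x * mu_y) / (sd_x * sd_y)
        corr2 = float(((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y)
    else:
        corr1 = corr2 = 0.0

    # information measures
    hx = float(-(px * _log2(px)).sum())
    hy = float(-(py * _log2(py)).sum())
    pxpy = px[:, None] * py[None, :]
    log_pxpy = _log2(pxpy)
    hxy1 = float(-(p * log_pxpy).sum())
    hxy2 = float(-(pxpy * log_pxpy).sum())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    mcc = _maximal_correlation_coefficient(p, px, py)

    return {
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": entropy,
        "glcm_dissimilarity": float((diff * p).sum()),
        "glcm_contrast": float(((i - j) ** 2 * p).sum()),
        "glcm_inversed_difference": float((p / (1.0 + diff)).sum()),
        "glcm_correlation1": corr1,
        "glcm_correlation2": corr2,
        "glcm_homogeneity": float((p / (1.0 + (i - j) ** 2)).sum()),
        "glcm_autocorrelation": float((i * j * p).sum()),
        "glcm_cluster_shade": float(((i + j - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_cluster_prominence": float(((i + j - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_of_squares": float(((i - mu_x) ** 2 * p).sum()),
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "glcm_sum_entropy": float(-(p_sum * _log2(p_sum)).sum()),
        "glcm_difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "glcm_difference_entropy": float(-(p_diff * _log2(p_diff)).sum()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_maximal_correlation_coefficient": mcc,
        "glcm_inverse_difference_normalized": float((p / (1.0 + diff / ng)).sum()),
        "glcm_inverse_difference_moment_normalized": float(
            (p / (1.0 + (i - j) ** 2 / ng**2)).sum()
        ),
    }


def _maximal_correlation_coefficient(p, px, py) -> float:
    """sqrt of the second-largest eigenvalue of Q(i,j)=sum_k p_ik p_jk/(px_i py_k)."""
    if p.shape[0] < 2:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        q = (p / px[:, None]) @ (p / py[None, :]).T
    q = np.nan_to_num(q, nan=0.0, posinf=0.0)
    eig = np.sort(np.real(np.linalg.eigvals(q)))
    return float(np.sqrt(max(0.0, eig[-2])))


def _weighted_matrix_features(matrix: np.ndarray, n_pixels: int, prefix: str, names) -> dict:
    """Shared GLRLM/GLSZM formula block (level i weighted 1-based, size j)."""
    total = float(matrix.sum())
    i = np.arange(1, matrix.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, matrix.shape[1] + 1, dtype=np.float64)[None, :]
    m = matrix.astype(np.float64)
    p = m / total
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    row = m.sum(axis=1)
    col = m.sum(axis=0)
    values = (
        float((m / j**2).sum()) / total,
        float((m * j**2).sum()) / total,
        float((row**2).sum()) / total,
        float((col**2).sum()) / total,
        total / n_pixels,
        float((m / i**2).sum()) / total,
        float((m * i**2).sum()) / total,
        float((m / (i**2 * j**2)).sum()) / total,
        float((m * i**2 / j**2).sum()) / total,
        float((m * j**2 / i**2).sum()) / total,
        float((m * i**2 * j**2).sum()) / total,
        float(((i - mu_i) ** 2 * p).sum()),
        float(((j - mu_j) ** 2 * p).sum()),
    )
    return dict(zip(names, values))


def glrlm_features(glrlm: GLRLM, n_pixels: int) -> dict[str, float]:
    """The 13 run-length features (run percentage needs the ROI pixel count)."""
    return _weighted_matrix_features(glrlm.matrix, n_pixels, "glrlm", GLRLM_NAMES)


def glszm_features(glszm: GLSZM, n_pixels: int) -> dict[str, float]:
    """The 13 size-zone features."""
    return _weighted_matrix_features(glszm.matrix, n_pixels, "glszm", GLSZM_NAMES)


def ngtdm_features(ngtdm: NGTDM) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity, strength."""
    n = ngtdm.n.astype(np.float64)
    s = ngtdm.s
    total = n.sum()
    present = np.flatnonzero(n > 0)
    p = n / total
    idx = (present + 1).astype(np.float64)  # 1-based level weights
    pi = p[present]
    si = s[present]
    ngp = present.size

    pisi = float((pi * si).sum())
    coarseness = 1.0 / pisi if pisi > 0 else COARSENESS_CAP
    coarseness = min(coarseness, COARSENESS_CAP)

    if ngp > 1:
        di = idx[:, None] - idx[None, :]
        pij = pi[:, None] * pi[None, :]
        contrast = float((pij * di**2).sum()) / (ngp * (ngp - 1)) * float(si.sum()) / total
        busy_den = float(np.abs(idx[:, None] * pi[:, None] - idx[None, :] * pi[None, :]).sum())
        busyness = pisi / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (
                np.abs(di)
                * (pi[:, None] * si[:, None] + pi[None, :] * si[None, :])
                / (pi[:, None] + pi[None, :])
            ).sum()
        ) / total
        s_sum = float(si.sum())
        strength = (
            float(((pi[:, None] + pi[None, :]) * di**2).sum()) / s_sum if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_coarseness": coarseness,
        "ngtdm_contrast": contrast,
        "ngtdm_busyness": busyness,
        "ngtdm_complexity": complexity,
        "ngtdm_strength": strength,
    }


def roi_texture_features(roi: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """Directional spread of co-occurrence contrast/correlation/dissimilarity.

    Per-direction GLCMs (not merged) each yield contrast, correlation
    ("covariance") and dissimilarity ("non-similarity"); the six features are
    the mean and population SD of each over the four directions.
    """
    per_dir = compute_glcm(roi, distance=distance, merge=False)
    contrasts, covariances, nonsims = [], [], []
    for g in per_dir:
        if g.matrix.sum() == 0:
            continue
        p, present = _glcm_support(g.normalized().matrix)
        idx = (present + 1).astype(np.float64)
        i, j = idx[:, None], idx[None, :]
        px, py = p.sum(axis=1), p.sum(axis=0)
        mu_x, mu_y = float((idx * px).sum()), float((idx * py).sum())
        sd_x = np.sqrt(float(((idx - mu_x) ** 2 * px).sum()))
        sd_y = np.sqrt(float(((idx - mu_y) ** 2 * py).sum()))
        contrasts.append(float(((i - j) ** 2 * p).sum()))
        covariances.append(
            float(((i - mu_x) * (j - mu_y) * p).sum()) / (sd_x * sd_y)
            if sd_x > 0 and sd_y > 0
            else 0.0
        )
        nonsims.append(float((np.abs(i - j) * p).sum()))
    if not contrasts:
        return {name: 0.0 for name in ROI_TEXTURE_NAMES}

    def mean_sd(vals):
        a = np.asarray(vals)
        return float(a.mean()), float(a.std())

    cm, cs = mean_sd(contrasts)
    vm, vs = mean_sd(covariances)
    nm, ns = mean_sd(nonsims)
    return {
        "roitex_contrast_mean": cm,
        "roitex_contrast_sd": cs,
        "roitex_covariance_mean": vm,
        "roitex_covariance_sd": vs,
        "roitex_nonsimilarity_mean": nm,
        "roitex_nonsimilarity_sd": ns,
    }
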