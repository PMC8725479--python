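"""Independent brute-force oracles for the texture matrices and features.

Everything here is written as literal per-pixel / per-cell loops, straight
from the definitions, sharing no code with the package implementation.  The
same documented conventions are used (1-based grey-level weights, log base 2,
population moments).
"""

from __future__ import annotations

import math

import numpy as np

N_LEVELS = 256
OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_glcm(levels, mask, angles=(0, 45, 90, 135), distance=1, symmetric=True):
    """Double loop over all pixel pairs with both ends in-mask."""
    rows, cols = levels.shape
    counts = np.zeros((N_LEVELS, N_LEVELS), dtype=np.int64)
    for angle in angles:
        dr, dc = OFFSETS[angle]
        dr, dc = dr * distance, dc * distance
        for r in range(rows):
            for c in range(cols):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                    counts[levels[r, c], levels[r2, c2]] += 1
                    if symmetric:
                        counts[levels[r2, c2], levels[r, c]] += 1
    return counts


def brute_glrlm(levels, mask, angles=(0, 45, 90, 135)):
    """Run starts are pixels whose predecessor along -d is invalid."""
    rows, cols = levels.shape
    max_len = max(rows, cols)
    matrix = np.zeros((N_LEVELS, max_len), dtype=np.int64)

    def valid(r, c):
        return 0 <= r < rows and 0 <= c < cols and mask[r, c]

    for angle in angles:
        dr, dc = OFFSETS[angle]
        for r in range(rows):
            for c in range(cols):
                if not mask[r, c]:
                    continue
                pr, pc = r - dr, c - dc
                if valid(pr, pc) and levels[pr, pc] == levels[r, c]:
                    continue  # not a run start
                length = 1
                nr, nc = r + dr, c + dc
                while valid(nr, nc) and levels[nr, nc] == levels[r, c]:
                    length += 1
                    nr, nc = nr + dr, nc + dc
                matrix[levels[r, c], length - 1] += 1
    last = int(np.flatnonzero(matrix.any(axis=0)).max()) + 1
    return matrix[:, :last]


def brute_glszm(levels, mask):
    """Explicit stack-based 8-connected flood fill per level."""
    rows, cols = levels.shape
    n_pixels = int(mask.sum())
    matrix = np.zeros((N_LEVELS, n_pixels), dtype=np.int64)
    seen = np.zeros_like(mask, dtype=bool)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c] or seen[r, c]:
                continue
            level = levels[r, c]
            stack = [(r, c)]
            seen[r, c] = True
            size = 0
            while stack:
                cr, cc = stack.pop()
                size += 1
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        nr, nc = cr + dr, cc + dc
                        if (
                            0 <= nr < rows
                            and 0 <= nc < cols
                            and mask[nr, nc]
                            and not seen[nr, nc]
                            and levels[nr, nc] == level
                        ):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
            matrix[level, size - 1] += 1
    last = int(np.flatnonzero(matrix.any(axis=0)).max()) + 1
    return matrix[:, :last]


def brute_ngtdm(levels, mask):
    """Per-pixel loop over the Chebyshev radius-1 neighbourhood."""
    rows, cols = levels.shape
    n = np.zeros(N_LEVELS, dtype=np.int64)
    s = np.zeros(N_LEVELS, dtype=np.float64)
    for r in range(rows):
        for c in range(cols):
            if not mask[r, c]:
                continue
            neigh = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == 0 and dc == 0:
                        continue
                    nr, nc = r + dr, c + dc
                    if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc]:
                        neigh.append(levels[nr, nc])
            if not neigh:
                continue
            n[levels[r, c]] += 1
            s[levels[r, c]] += abs(levels[r, c] - sum(neigh) / len(neigh))
    return n, s


# ---------------------------------------------------------------------------
# literal-formula feature oracles (explicit loops over matrix cells)


def _entropy(ps):
    return -sum(p * math.log2(p) for p in ps if p > 0)


def oracle_histogram_features(levels, mask):
    x = sorted(levels[mask].tolist())
    n = len(x)
    counts = {}
    for v in x:
        counts[v] = counts.get(v, 0) + 1
    p = {v: c / n for v, c in counts.items()}
    mean = sum(x) / n
    var = sum((v - mean) ** 2 for v in x) / n
    sd = math.sqrt(var)
    skew = sum((v - mean) ** 3 for v in x) / n / sd**3 if sd > 0 else 0.0
    kurt = sum((v - mean) ** 4 for v in x) / n / var**2 - 3 if var > 0 else 0.0
    if n % 2:
        median = x[n // 2]
    else:
        median = (x[n // 2 - 1] + x[n // 2]) / 2
    return {
        "hist_energy": float(sum(v**2 for v in x)),
        "hist_entropy": _entropy(p.values()),
        "hist_kurtosis": kurt,
        "hist_mean": mean,
        "hist_median_absolute_deviation": sum(abs(v - median) for v in x) / n,
        "hist_median": float(median),
        "hist_range": float(max(x) - min(x)),
        "hist_uniformity": sum(q**2 for q in p.values()),
        "hist_variance": var,
        "hist_root_mean_square": math.sqrt(sum(v**2 for v in x) / n),
        "hist_skewness": skew,
        "hist_deviation": sd,
        "hist_histogram_kurtosis": kurt,
        "hist_histogram_mean": mean,
        "hist_histogram_variance": var,
        "hist_histogram_skewness": skew,
    }


def oracle_glcm_features(counts):
    """All 23 co-occurrence features from a count matrix, cell by cell."""
    total = counts.sum()
    cells = [
        (i + 1, j + 1, counts[i, j] / total)
        for i in range(N_LEVELS)
        for j in range(N_LEVELS)
        if counts[i, j] > 0
    ]
    present_i = sorted({i for i, _, _ in cells} | {j for _, j, _ in cells})
    ng = len(present_i)
    px = {i: 0.0 for i in present_i}
    py = {j: 0.0 for j in present_i}
    for i, j, p in cells:
        px[i] += p
        py[j] += p
    mu_x = sum(i * p for i, p in px.items())
    mu_y = sum(j * p for j, p in py.items())
    var_x = sum((i - mu_x) ** 2 * p for i, p in px.items())
    var_y = sum((j - mu_y) ** 2 * p for j, p in py.items())
    sd_x, sd_y = math.sqrt(var_x), math.sqrt(var_y)

    p_sum: dict[int, float] = {}
    p_diff: dict[int, float] = {}
    for i, j, p in cells:
        p_sum[i + j] = p_sum.get(i + j, 0.0) + p
        p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + p
    sum_avg = sum(k * p for k, p in p_sum.items())
    diff_avg = sum(k * p for k, p in p_diff.items())

    entropy = _entropy([p for _, _, p in cells])
    hx = _entropy(px.values())
    hy = _entropy(py.values())
    hxy1 = -sum(p * math.log2(px[i] * py[j]) for i, j, p in cells if px[i] * py[j] > 0)
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j])
        for i in present_i
        for j in present_i
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    # maximal correlation coefficient
    if ng >= 2:
        pmat = {(i, j): p for i, j, p in cells}
        q = np.zeros((ng, ng))
        for a, i in enumerate(present_i):
            for b, j in enumerate(present_i):
                q[a, b] = sum(
                    pmat.get((i, k), 0.0) * pmat.get((j, k), 0.0) / (px[i] * py[k])
                    for k in present_i
                    if px[i] > 0 and py[k] > 0
                )
        eig = sorted(np.real(np.linalg.eigvals(q)))
        mcc = math.sqrt(max(0.0, eig[-2]))
    else:
        mcc = 0.0

    if sd_x > 0 and sd_y > 0:
        corr1 = (sum(i * j * p for i, j, p in cells) - mu_x * mu_y) / (sd_x * sd_y)
        corr2 = sum((i - mu_x) * (j - mu_y) * p for i, j, p in cells) / (sd_x * sd_y)
    else:
        corr1 = corr2 = 0.0

    return {
        "glcm_energy": sum(p**2 for _, _, p in cells),
        "glcm_entropy": entropy,
        "glcm_dissimilarity": sum(abs(i - j) * p for i, j, p in cells),
        "glcm_contrast": sum((i - j) ** 2 * p for i, j, p in cells),
        "glcm_inversed_difference": sum(p / (1 + abs(i - j)) for i, j, p in cells),
        "glcm_correlation1": corr1,
        "glcm_correlation2": corr2,
        "glcm_homogeneity": sum(p / (1 + (i - j) ** 2) for i, j, p in cells),
        "glcm_autocorrelation": sum(i * j * p for i, j, p in cells),
        "glcm_cluster_shade": sum((i + j - mu_x - mu_y) ** 3 * p for i, j, p in cells),
        "glcm_cluster_prominence": sum((i + j - mu_x - mu_y) ** 4 * p for i, j, p in cells),
        "glcm_maximum_probability": max(p for _, _, p in cells),
        "glcm_sum_of_squares": sum((i - mu_x) ** 2 * p for i, j, p in cells),
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": sum((k - sum_avg) ** 2 * p for k, p in p_sum.items()),
        "glcm_sum_entropy": _entropy(p_sum.values()),
        "glcm_difference_variance": sum((k - diff_avg) ** 2 * p for k, p in p_diff.items()),
        "glcm_difference_entropy": _entropy(p_diff.values()),
        "glcm_imc1": imc1,
        "glcm_imc2": imc2,
        "glcm_maximal_correlation_coefficient": mcc,
        "glcm_inverse_difference_normalized": sum(p / (1 + abs(i - j) / ng) for i, j, p in cells),
        "glcm_inverse_difference_moment_normalized": sum(
            p / (1 + (i - j) ** 2 / ng**2) for i, j, p in cells
        ),
    }


def _oracle_run_zone(matrix, n_pixels, prefix):
    total = matrix.sum()
    cells = [
        (i + 1, j + 1, int(matrix[i, j]))
        for i in range(matrix.shape[0])
        for j in range(matrix.shape[1])
        if matrix[i, j] > 0
    ]
    mu_i = sum(i * c for i, _, c in cells) / total
    mu_j = sum(j * c for _, j, c in cells) / total
    row = {}
    col = {}
    for i, j, c in cells:
        row[i] = row.get(i, 0) + c
        col[j] = col.get(j, 0) + c
    return {
        f"{prefix}_0": sum(c / j**2 for _, j, c in cells) / total,
        f"{prefix}_1": sum(c * j**2 for _, j, c in cells) / total,
        f"{prefix}_2": sum(v**2 for v in row.values()) / total,
        f"{prefix}_3": sum(v**2 for v in col.values()) / total,
        f"{prefix}_4": total / n_pixels,
        f"{prefix}_5": sum(c / i**2 for i, _, c in cells) / total,
        f"{prefix}_6": sum(c * i**2 for i, _, c in cells) / total,
        f"{prefix}_7": sum(c / (i**2 * j**2) for i, j, c in cells) / total,
        f"{prefix}_8": sum(c * i**2 / j**2 for i, j, c in cells) / total,
        f"{prefix}_9": sum(c * j**2 / i**2 for i, j, c in cells) / total,
        f"{prefix}_10": sum(c * i**2 * j**2 for i, j, c in cells) / total,
        f"{prefix}_11": sum((i - mu_i) ** 2 * c for i, _, c in cells) / total,
        f"{prefix}_12": sum((j - mu_j) ** 2 * c for _, j, c in cells) / total,
    }


def oracle_glrlm_features(matrix, n_pixels):
    return _oracle_run_zone(matrix, n_pixels, "glrlm")


def oracle_glszm_features(matrix, n_pixels):
    return _oracle_run_zone(matrix, n_pixels, "glszm")


def oracle_ngtdm_features(n, s, cap=1.0e6):
    total = int(n.sum())
    present = [i for i in range(N_LEVELS) if n[i] > 0]
    pi = {i + 1: n[i] / total for i in present}
    si = {i + 1: s[i] for i in present}
    ngp = len(present)
    pisi = sum(pi[i] * si[i] for i in pi)
    coarseness = min(1.0 / pisi if pisi > 0 else cap, cap)
    if ngp > 1:
        contrast = (
            sum(pi[i] * pi[j] * (i - j) ** 2 for i in pi for j in pi)
            / (ngp * (ngp - 1))
            * sum(si.values())
            / total
        )
        busy_den = sum(abs(i * pi[i] - j * pi[j]) for i in pi for j in pi)
        busyness = pisi / busy_den if busy_den > 0 else 0.0
        complexity = (
            sum(
                abs(i - j) * (pi[i] * si[i] + pi[j] * si[j]) / (pi[i] + pi[j])
                for i in pi
                for j in pi
            )
            / total
        )
        s_sum = sum(si.values())
        strength = (
            sum((pi[i] + pi[j]) * (i - j) ** 2 for i in pi for j in pi) / s_sum
            if s_sum > 0
            else 0.0
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


def oracle_roi_texture(levels, mask, angles=(0, 45, 90, 135)):
    """Per-direction contrast/correlation/dissimilarity, then mean and SD."""
    contrasts, covs, nonsims = [], [], []
    for angle in angles:
        counts = brute_glcm(levels, mask, angles=(angle,))
        if counts.sum() == 0:
            continue
        f = oracle_glcm_features(counts)
        contrasts.append(f["glcm_contrast"])
        covs.append(f["glcm_correlation2"])
        nonsims.append(f["glcm_dissimilarity"])

    def mean_sd(vals):
        m = sum(vals) / len(vals)
        return m, math.sqrt(sum((v - m) ** 2 for v in vals) / len(vals))

    cm, cs = mean_sd(contrasts)
    vm, vs = mean_sd(covs)
    nm, ns = mean_sd(nonsims)
    return {
        "roitex_contrast_mean": cm,
        "roitex_contrast_sd": cs,
        "roitex_covariance_mean": vm,
        "roitex_covariance_sd": vs,
        "roitex_nonsimilarity_mean": nm,
        "roitex_nonsimilarity_sd": ns,
    }


def brute_auc(scores, labels):
    """Exhaustive concordant-pair count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
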