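"""Brute-force reference implementations used only by the test suite.

Each oracle re-derives a quantity from first principles (explicit loops,
pair enumeration, exhaustive scans) independently of the package's
vectorized implementations.
"""

import numpy as np


def mann_whitney_auc(scores, labels):
    """AUC as the normalized count of correctly ordered (pos, neg) pairs,
    ties counted half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    count = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                count += 1.0
            elif sp == sn:
                count += 0.5
    return count / (len(pos) * len(neg))


def exhaustive_best_threshold(scores, labels, weight=0.5):
    """Scan every candidate threshold (midpoints between consecutive unique
    scores, the extremes included) maximizing 2[w(1-fpr) + (1-w)tpr]; ties
    broken toward lower fpr, then toward the higher threshold."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    uniq = np.sort(np.unique(scores))[::-1]
    candidates = [uniq[0] + 1.0]
    for j in range(len(uniq) - 1):
        candidates.append((uniq[j] + uniq[j + 1]) / 2.0)
    candidates.append(uniq[-1])
    best = None
    for theta in candidates:
        tp = fp = tn = fn = 0
        for s, y in zip(scores, labels):
            if s >= theta:
                if y == 1:
                    tp += 1
                else:
                    fp += 1
            else:
                if y == 1:
                    fn += 1
                else:
                    tn += 1
        fpr = fp / (fp + tn)
        tpr = tp / (tp + fn)
        j_stat = 2.0 * (weight * (1.0 - fpr) + (1.0 - weight) * tpr)
        key = (j_stat, -fpr, theta)
        if best is None or key > best[0]:
            best = (key, theta)
    return best[1]


def confusion_sens_spec(scores, labels, threshold):
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= threshold
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 1:
            fn += 1
        else:
            tn += 1
    return tp / (tp + fn), tn / (tn + fp)


def haralick_by_pair_enumeration(pixels, mask, offset, n_levels):
    """GLCM + 18 statistics from explicit per-pixel-pair loops.

    Mirrors the documented conventions (min-max quantization over in-mask
    pixels, symmetric accumulation, unit distance, natural-log entropies)
    but shares no code with the package implementation.
    """
    pixels = np.asarray(pixels, float)
    mask = np.asarray(mask, bool)
    vals = pixels[mask]
    lo, hi = vals.min(), vals.max()
    q = np.full(pixels.shape, -1, dtype=int)
    for r in range(pixels.shape[0]):
        for c in range(pixels.shape[1]):
            if mask[r, c]:
                if hi == lo:
                    q[r, c] = 0
                else:
                    level = int((pixels[r, c] - lo) / (hi - lo) * n_levels)
                    q[r, c] = min(level, n_levels - 1)
    dr, dc = offset
    P = np.zeros((n_levels, n_levels))
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] >= 0 and q[r2, c2] >= 0:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    if P.sum() == 0:
        return P, np.zeros(18)
    P = P / P.sum()

    L = n_levels
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))

    p_sum = np.zeros(2 * L - 1)
    p_diff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            p_sum[i + j] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]

    def entropy_of(p):
        return -sum(v * np.log(v) for v in np.ravel(p) if v > 0)

    energy = (P ** 2).sum()
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    correlation = (sum((i - mu) * (j - mu) * P[i, j]
                       for i in range(L) for j in range(L)) / var) if var > 0 else 0.0
    homogeneity = sum(P[i, j] / (1 + (i - j) ** 2)
                      for i in range(L) for j in range(L))
    sum_average = sum(k * p_sum[k] for k in range(2 * L - 1))
    sum_variance = sum((k - sum_average) ** 2 * p_sum[k] for k in range(2 * L - 1))
    sum_entropy = entropy_of(p_sum)
    entropy = entropy_of(P)
    diff_mean = sum(k * p_diff[k] for k in range(L))
    diff_variance = sum((k - diff_mean) ** 2 * p_diff[k] for k in range(L))
    diff_entropy = entropy_of(p_diff)
    hxy1 = -sum(P[i, j] * np.log(px[i] * px[j])
                for i in range(L) for j in range(L) if px[i] * px[j] > 0)
    hxy2 = -sum(px[i] * px[j] * np.log(px[i] * px[j])
                for i in range(L) for j in range(L) if px[i] * px[j] > 0)
    hx = entropy_of(px)
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))
    autocorrelation = sum(i * j * P[i, j] for i in range(L) for j in range(L))
    cluster_shade = sum((i + j - 2 * mu) ** 3 * P[i, j]
                        for i in range(L) for j in range(L))
    cluster_prominence = sum((i + j - 2 * mu) ** 4 * P[i, j]
                             for i in range(L) for j in range(L))
    dissimilarity = sum(abs(i - j) * P[i, j] for i in range(L) for j in range(L))
    max_prob = P.max()

    feats = np.array([energy, contrast, correlation, var, homogeneity,
                      sum_average, sum_variance, sum_entropy, entropy,
                      diff_variance, diff_entropy, imc1, imc2,
                      autocorrelation, cluster_shade, cluster_prominence,
                      dissimilarity, max_prob])
    return P, feats


def grid_mle_adc(signals, b_values, d_grid):
    """Per-pixel grid maximization of the Gaussian likelihood: for each
    candidate D, S0 is profiled out in closed form; returns argmin-SSR D."""
    signals = np.asarray(signals, float)       # (n_b, n_pix)
    b = np.asarray(b_values, float)
    best_d = np.zeros(signals.shape[1])
    best_ssr = np.full(signals.shape[1], np.inf)
    for d in d_grid:
        e = np.exp(-b * d)
        s0 = signals.T @ e / (e @ e)
        ssr = ((signals - np.outer(e, s0)) ** 2).sum(axis=0)
        better = ssr < best_ssr
        best_ssr[better] = ssr[better]
        best_d[better] = d
    return best_d
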