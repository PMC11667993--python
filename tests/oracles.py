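"""Naive brute-force reference implementations used as independent oracles.

Every function here recomputes a pipeline quantity with explicit Python
loops and no shared code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np


def naive_quantify(frames, rate, roi, theta, d, clip_seconds):
    """Triple-loop reference for quantify_session.

    frames: (n, H, W) uint8; roi: (x0, y0, x1, y1) half-open.
    """
    x0, y0, x1, y1 = roi
    rate = int(rate)
    n_blocks = int(round(clip_seconds))
    counts = []
    for b in range(n_blocks):
        block = frames[b * rate : (b + 1) * rate]
        kept = []
        for i in range(1, d + 1):
            idx_1based = round(1 + (i - 1) * (rate - 1) / (d - 1))
            kept.append(block[idx_1based - 1])
        for a, bb in zip(kept[:-1], kept[1:]):
            c = 0
            for yy in range(y0, y1):
                for xx in range(x0, x1):
                    if abs(int(bb[yy, xx]) - int(a[yy, xx])) > theta:
                        c += 1
            counts.append(c)
    return counts


def naive_windows(m, w, hop):
    out = []
    start = 0
    while start + w <= len(m):
        out.append(list(m[start : start + w]))
        start += hop
    return out


def naive_windowed_variance(m, w, hop):
    variances = []
    for win in naive_windows(m, w, hop):
        mean = sum(win) / w
        variances.append(sum((v - mean) ** 2 for v in win) / w)
    return sum(variances) / len(variances)


def naive_windowed_entropy(m, w, hop):
    entropies = []
    for win in naive_windows(m, w, hop):
        counts: dict[int, int] = {}
        for v in win:
            counts[v] = counts.get(v, 0) + 1
        se = 0.0
        for c in counts.values():
            p = c / w
            se -= p * math.log2(p)
        entropies.append(se)
    return sum(entropies) / len(entropies)


def naive_metrics(y_true, y_pred, positive=1):
    tp = fn = tn = fp = 0
    for t, p in zip(y_true, y_pred):
        if t == positive:
            if p == positive:
                tp += 1
            else:
                fn += 1
        else:
            if p == positive:
                fp += 1
            else:
                tn += 1
    acc = (tp + tn) / len(y_true)
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return acc, sens, spec


def naive_auc(y_true, scores, positive=1):
    """Mann-Whitney formulation of the ROC area, with tie correction."""
    pos = [s for t, s in zip(y_true, scores) if t == positive]
    neg = [s for t, s in zip(y_true, scores) if t != positive]
    if not pos or not neg:
        return float("nan")
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def naive_welch(a, b):
    """Two-sided Welch t-test from the textbook formulas."""
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p
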