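"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles against the mathematical
definitions — set counting for Tanimoto, a Gotoh three-state dynamic
program for affine-gap alignment, exhaustive confusion-matrix enumeration,
O(P*N) pair counting for AUC, and the step-wise construction for the area
under the precision-recall curve.  None of it calls the package under test.
"""

from __future__ import annotations

import numpy as np

NEG_INF = float("-inf")


def tanimoto_sets(fp_a, fp_b) -> float:
    """|A ∩ B| / |A ∪ B| via explicit bit-index sets."""
    a = {i for i, b in enumerate(fp_a) if b}
    b = {i for i, v in enumerate(fp_b) if v}
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def affine_dp_score(seq_a, seq_b, sub, gap_open, gap_extend, mode="local") -> float:
    """Optimal affine-gap alignment score by the Gotoh three-state DP.

    ``sub(x, y)`` is the substitution score.  A gap of length L costs
    ``gap_open + (L - 1) * gap_extend``.  Local mode returns the best score
    of any sub-alignment (>= 0); global mode the end-to-end optimum.
    """
    n, m = len(seq_a), len(seq_b)
    local = mode == "local"
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_b (seq_a residue vs gap)
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in seq_a
    M[0, 0] = 0.0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = gap_open + (i - 1) * gap_extend
        for j in range(1, m + 1):
            Iy[0, j] = gap_open + (j - 1) * gap_extend
    else:
        M[:, 0] = 0.0
        M[0, :] = 0.0
    best = 0.0 if local else NEG_INF
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            if local:
                M[i, j] = max(M[i, j], s)
                if M[i, j] < 0:
                    M[i, j] = 0.0
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            if local and M[i, j] > best:
                best = M[i, j]
    if local:
        return best
    return max(M[n, m], Ix[n, m], Iy[n, m])


def confusion_precision_recall(y_true, y_score, threshold=0.5):
    """Precision and recall by explicit enumeration of the four cells."""
    tp = fp = fn = tn = 0
    for t, s in zip(y_true, y_score):
        pred = s >= threshold
        if pred and t == 1:
            tp += 1
        elif pred and t == 0:
            fp += 1
        elif not pred and t == 1:
            fn += 1
        else:
            tn += 1
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return precision, recall


def auc_pair_counting(y_true, y_score) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg), ties counting half."""
    pos = [s for t, s in zip(y_true, y_score) if t == 1]
    neg = [s for t, s in zip(y_true, y_score) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def aupr_stepwise(y_true, y_score) -> float:
    """Area under the precision-recall curve, step-wise over distinct
    score thresholds in descending order (the average-precision sum)."""
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score)
    n_pos = int(np.sum(y_true == 1))
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(y_score.tolist()), reverse=True):
        pred = y_score >= t
        tp = int(np.sum(pred & (y_true == 1)))
        precision = tp / int(np.sum(pred))
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area
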