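"""Independent brute-force oracles used by unit and acceptance tests.

These are deliberately naive re-implementations (explicit loops, no
shared code with the package) so they can arbitrate the vectorized
implementations.
"""

from __future__ import annotations


def brute_force_run_selection(flags):
    """Enumerate every maximal run of True and apply the documented
    tie-breaks: longest wins, earliest among equals, lower-middle centre.

    Returns (start, end_inclusive, central, length) or None.
    """
    runs = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not runs:
        return None
    best = None
    for start, end in runs:
        length = end - start + 1
        if best is None or length > best[3]:
            best = (start, end, start + (length - 1) // 2, length)
    return best


def _iou(a, b):
    ra0, ca0, ra1, ca1 = a
    rb0, cb0, rb1, cb1 = b
    ih = min(ra1, rb1) - max(ra0, rb0)
    iw = min(ca1, cb1) - max(ca0, cb0)
    if ih <= 0 or iw <= 0:
        return 0.0
    inter = ih * iw
    area_a = (ra1 - ra0) * (ca1 - ca0)
    area_b = (rb1 - rb0) * (cb1 - cb0)
    return inter / (area_a + area_b - inter)


def brute_force_precision_recall(predictions, truths, iou_threshold):
    """Greedy confidence-descending matching with explicit loops.

    ``predictions``: per image, list of (box, confidence) tuples;
    ``truths``: per image, list of boxes.
    """
    tp = fp = n_truth = 0
    for preds, gts in zip(predictions, truths):
        n_truth += len(gts)
        order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
        available = list(range(len(gts)))
        for i in order:
            best_j, best_iou = None, -1.0
            for j in available:
                v = _iou(preds[i][0], gts[j])
                if v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None and best_iou >= iou_threshold:
                available.remove(best_j)
                tp += 1
            else:
                fp += 1
    n_pred = tp + fp
    precision = tp / n_pred if n_pred else 1.0
    recall = tp / n_truth if n_truth else 1.0
    return precision, recall


def mean_sd_of_magnitudes(offsets):
    """Spreadsheet-style mean and sample SD of Euclidean magnitudes."""
    mags = [(x * x + y * y) ** 0.5 for x, y in offsets]
    n = len(mags)
    mean = sum(mags) / n
    if n < 2:
        return mean, 0.0
    var = sum((m - mean) ** 2 for m in mags) / (n - 1)
    return mean, var ** 0.5
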