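"""Independent brute-force reference implementations used as test oracles.

Deliberately simple and loop-based; they must stay independent of the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def brute_confusion(true, pred, n_classes: int) -> np.ndarray:
    m = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(true, pred):
        m[int(t), int(p)] += 1
    return m


def brute_tolerance_accuracy(true, pred, tol: int) -> float:
    n = len(true)
    ok = 0
    for t in range(n):
        lo, hi = max(0, t - tol), min(n, t + tol + 1)
        if any(true[tp] == pred[t] for tp in range(lo, hi)):
            ok += 1
    return ok / n


def brute_offsets(true, pred, rate_hz: float):
    offsets = []
    unmatched = []
    true = np.asarray(true)
    for t in range(len(true)):
        if pred[t] == true[t]:
            continue
        where = np.flatnonzero(true == pred[t])
        if where.size == 0:
            unmatched.append(t)
        else:
            offsets.append(np.min(np.abs(where - t)) * 1000.0 / rate_hz)
    return sorted(offsets), unmatched


def brute_rejection(correct, certainty, threshold: float) -> dict:
    n_total = len(correct)
    n_unknown = n_cu = n_wu = 0
    kept_correct = kept_total = 0
    for ok, c in zip(correct, certainty):
        if c <= threshold:
            n_unknown += 1
            if ok:
                n_cu += 1
            else:
                n_wu += 1
        else:
            kept_total += 1
            if ok:
                kept_correct += 1
    return {
        "n_unknown": n_unknown,
        "n_correct_to_unknown": n_cu,
        "n_wrong_to_unknown": n_wu,
        "accuracy_retained": kept_correct / kept_total if kept_total else None,
        "n_total": n_total,
    }
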