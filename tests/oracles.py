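"""Independent per-position loop oracles for every loss and metric.

These are deliberately written as plain-Python scalar loops over positions and
classes — no vectorisation, no shared code with the package — so they can act
as an independent check of the library's array implementations.
"""

from __future__ import annotations

import math

EPS = 1e-6


def _clip(v: float, eps: float = EPS) -> float:
    return min(max(v, eps), 1.0 - eps)


def _positions(p):
    """Flatten one item's (spatial..., C) nested structure to a list of rows."""
    import numpy as np

    arr = np.asarray(p, dtype=float)
    return arr.reshape(-1, arr.shape[-1]).tolist()


def _p_true(row_p, row_y):
    return sum(pc * yc for pc, yc in zip(row_p, row_y))


# -- distribution family ----------------------------------------------------

def ce_item(p, y, eps: float = EPS) -> float:
    rows_p, rows_y = _positions(p), _positions(y)
    total = 0.0
    for rp, ry in zip(rows_p, rows_y):
        total += -math.log(_clip(_p_true(rp, ry), eps))
    return total / len(rows_p)


def focal_item(p, y, alpha, gamma, eps: float = EPS) -> float:
    rows_p, rows_y = _positions(p), _positions(y)
    total = 0.0
    for rp, ry in zip(rows_p, rows_y):
        pt = _clip(_p_true(rp, ry), eps)
        if alpha is None:
            w = 1.0
        elif isinstance(alpha, (int, float)):
            w = alpha if ry[0] == 0.0 else 1.0 - alpha
        else:
            w = sum(a * yc for a, yc in zip(alpha, ry))
        total += w * (1.0 - pt) ** gamma * -math.log(pt)
    return total / len(rows_p)


def modified_focal_item(p, y, delta, gamma, eps: float = EPS) -> float:
    rows_p, rows_y = _positions(p), _positions(y)
    total = 0.0
    for rp, ry in zip(rows_p, rows_y):
        pt = _clip(_p_true(rp, ry), eps)
        w = delta if ry[0] == 0.0 else 1.0 - delta
        total += w * (1.0 - pt) ** gamma * -math.log(pt)
    return total / len(rows_p)


def asymmetric_focal_item(p, y, delta, gamma, rare, eps: float = EPS) -> float:
    rows_p, rows_y = _positions(p), _positions(y)
    total = 0.0
    for rp, ry in zip(rows_p, rows_y):
        pt = _clip(_p_true(rp, ry), eps)
        true_class = ry.index(1.0)
        if true_class in rare:
            total += delta * -math.log(pt)
        else:
            total += (1.0 - delta) * (1.0 - pt) ** gamma * -math.log(pt)
    return total / len(rows_p)


# -- region family ----------------------------------------------------------

def soft_counts_item(p, y, c: int):
    rows_p, rows_y = _positions(p), _positions(y)
    tp = fp = fn = 0.0
    for rp, ry in zip(rows_p, rows_y):
        tp += rp[c] * ry[c]
        fp += rp[c] * (1.0 - ry[c])
        fn += (1.0 - rp[c]) * ry[c]
    return tp, fp, fn


def tversky_item(p, y, c, alpha, beta, eps: float = EPS) -> float:
    tp, fp, fn = soft_counts_item(p, y, c)
    return (tp + eps) / (tp + alpha * fp + beta * fn + eps)


def dice_item(p, y, c, eps: float = EPS) -> float:
    tp, fp, fn = soft_counts_item(p, y, c)
    return (2.0 * tp + eps) / (2.0 * tp + fp + fn + eps)


def region_loss_item(p, y, alpha, beta, exponent, eps: float = EPS) -> float:
    n_classes = len(_positions(p)[0])
    return sum(
        (1.0 - tversky_item(p, y, c, alpha, beta, eps)) ** exponent
        for c in range(n_classes)
    )


def asymmetric_region_loss_item(p, y, delta, gamma, rare,
                                eps: float = EPS) -> float:
    n_classes = len(_positions(p)[0])
    total = 0.0
    for c in range(n_classes):
        lm = 1.0 - tversky_item(p, y, c, delta, 1.0 - delta, eps)
        total += lm ** (1.0 - gamma) if c in rare else lm
    return total


# -- compound family --------------------------------------------------------

def combo_item(p, y, combo_alpha, beta, eps: float = EPS) -> float:
    rows_p, rows_y = _positions(p), _positions(y)
    mce = 0.0
    for rp, ry in zip(rows_p, rows_y):
        pt = _clip(_p_true(rp, ry), eps)
        w = beta if ry[0] == 0.0 else 1.0 - beta
        mce += w * -math.log(pt)
    mce /= len(rows_p)
    n_classes = len(rows_p[0])
    dsc = sum(dice_item(p, y, c, eps) for c in range(1, n_classes)) / (n_classes - 1)
    return combo_alpha * mce - (1.0 - combo_alpha) * dsc


def hybrid_item(p, y, lam, alpha, focal_gamma, tversky_beta, tversky_gamma,
                eps: float = EPS) -> float:
    f = focal_item(p, y, alpha, focal_gamma, eps)
    ft = region_loss_item(p, y, 1.0 - tversky_beta, tversky_beta,
                          1.0 / tversky_gamma, eps)
    return lam * f + (1.0 - lam) * ft


def unified_sym_item(p, y, lam, delta, gamma, eps: float = EPS) -> float:
    mf = modified_focal_item(p, y, delta, gamma, eps)
    mft = region_loss_item(p, y, delta, 1.0 - delta, 1.0 - gamma, eps)
    return lam * mf + (1.0 - lam) * mft


def unified_asym_item(p, y, lam, delta, gamma, rare, eps: float = EPS) -> float:
    maf = asymmetric_focal_item(p, y, delta, gamma, rare, eps)
    maft = asymmetric_region_loss_item(p, y, delta, gamma, rare, eps)
    return lam * maf + (1.0 - lam) * maft


# -- hard metrics -----------------------------------------------------------

def hard_metrics(pred, true, num_classes):
    """Per-class (dsc, iou, recall, precision) with None where undefined."""
    import numpy as np

    pred = np.asarray(pred).ravel().tolist()
    true = np.asarray(true).ravel().tolist()
    out = []
    for c in range(num_classes):
        tp = sum(1 for a, b in zip(pred, true) if a == c and b == c)
        fp = sum(1 for a, b in zip(pred, true) if a == c and b != c)
        fn = sum(1 for a, b in zip(pred, true) if a != c and b == c)
        metrics = {}
        for name, num, den in (
            ("dsc", 2 * tp, 2 * tp + fp + fn),
            ("iou", tp, tp + fp + fn),
            ("recall", tp, tp + fn),
            ("precision", tp, tp + fp),
        ):
            metrics[name] = num / den if den > 0 else None
        out.append(metrics)
    return out
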