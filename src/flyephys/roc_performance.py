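"""Convergence-ratio scores and ROC/AUC processing performance.

Presynaptic-to-postsynaptic transmission is scored by a family of
"convergence ratios" over a grid of 8900 lag tolerances delta (0.01 to 0.9 s
in 1e-4 steps, half-open): for each delta, the fraction of presynaptic
10-ms bins whose event is followed by a postsynaptic event within the lag
window.  Pooling the per-delta scores of condition trains against
rate-matched null trains and computing the tie-corrected ROC AUC yields a
single scalar "processing performance": 0.5 means the condition is
indistinguishable from the null, 1 means perfect discrimination.

The convergence-ratio construction is deliberately kept behind a strategy
function so alternative score definitions can be swapped without touching
the ROC code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

DELTA_START = 0.01
DELTA_STOP = 0.9
DELTA_STEP = 1e-4
BIN_WIDTH_S = 0.010


def delta_grid(
    start: float = DELTA_START, stop: float = DELTA_STOP, step: float = DELTA_STEP
) -> np.ndarray:
    """Half-open arithmetic grid [start, stop) of lag tolerances in seconds.

    The defaults give exactly 8900 values, 0.01 to 0.8999.
    """
    n = int(round((stop - start) / step))
    return start + step * np.arange(n)


def convergence_ratio(pre_signal, post_signal, delta: float, bin_s: float = BIN_WIDTH_S) -> float:
    """Fraction of presynaptic event bins answered postsynaptically within delta.

    Both signals are equal-length 0/1 vectors on a ``bin_s`` grid.  A
    presynaptic bin i counts as "converged" if any postsynaptic bin in
    [i, i + ceil(delta/bin_s)] is 1.  Raises on an empty presynaptic signal.
    """
    pre = np.asarray(pre_signal)
    post = np.asarray(post_signal)
    if pre.shape != post.shape:
        raise ValueError("pre and post signals must have equal length")
    pre_idx = np.nonzero(pre)[0]
    if pre_idx.size == 0:
        raise ValueError("presynaptic signal has no events; ratio undefined")
    lag = int(np.ceil(delta / bin_s))
    # cumulative count of post events allows O(1) any-in-window queries
    csum = np.concatenate(([0], np.cumsum(post != 0)))
    hi = np.minimum(pre_idx + lag + 1, post.size)
    hits = csum[hi] - csum[pre_idx]
    return float(np.mean(hits > 0))


def convergence_scores(pre_signal, post_signal, grid=None, bin_s: float = BIN_WIDTH_S):
    """Convergence ratios over the whole delta grid, computed in one pass.

    Equivalent to ``[convergence_ratio(pre, post, d) for d in grid]`` but
    shares the window bookkeeping: the ratio as a function of the integer lag
    is a step function, evaluated once per distinct lag.
    """
    if grid is None:
        grid = delta_grid()
    grid = np.asarray(grid, dtype=float)
    lags = np.ceil(grid / bin_s).astype(int)
    out = np.empty(grid.size)
    cache: dict[int, float] = {}
    for i, lag in enumerate(lags):
        if lag not in cache:
            cache[lag] = convergence_ratio(pre_signal, post_signal, lag * bin_s, bin_s)
        out[i] = cache[lag]
    return out


@dataclass
class RocResult:
    """ROC curve (FPR/TPR per threshold) and its tie-corrected AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_positive: int
    n_negative: int


def roc_auc(scores, labels) -> RocResult:
    """Tie-corrected ROC AUC via the Mann-Whitney rank statistic.

    AUC = (R_+ - n_+(n_+ + 1)/2) / (n_+ n_-) with R_+ the sum of mid-ranks of
    positive-class scores; ties contribute one half, so the value equals the
    trapezoidal area under the ROC curve.  Raises if only one class is
    present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))

    # explicit curve at each distinct threshold (descending)
    order = np.argsort(-s, kind="mergesort")
    y_sorted = y[order]
    s_sorted = s[order]
    distinct = np.nonzero(np.diff(s_sorted))[0]
    cut = np.concatenate([distinct, [y.size - 1]])
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(~y_sorted)[cut]
    return RocResult(
        thresholds=s_sorted[cut],
        fpr=np.concatenate(([0.0], fp / n_neg)),
        tpr=np.concatenate(([0.0], tp / n_pos)),
        auc=auc,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def rate_matched_poisson_signal(reference_signal, rng, bin_s: float = BIN_WIDTH_S):
    """Null train: Poisson events at the reference's event rate, binarized alike."""
    ref = np.asarray(reference_signal)
    n_events = int((ref != 0).sum())
    duration = ref.size * bin_s
    if n_events == 0:
        return np.zeros_like(ref)
    times = np.sort(rng.uniform(0.0, duration, size=rng.poisson(n_events)))
    sig = np.zeros(ref.size, dtype=np.int8)
    idx = np.floor(times / bin_s).astype(int)
    sig[idx[idx < ref.size]] = 1
    return sig


def processing_performance(
    condition_trains,
    null_trains,
    reference_signal,
    grid=None,
    score_fn=convergence_scores,
) -> RocResult:
    """Pooled-score AUC separating condition trains from null trains.

    Every train (binary signal) in each class is scored against the shared
    reference train at every delta of the grid; the pooled per-delta scores
    with class labels enter a single tie-corrected ROC.
    """
    if grid is None:
        grid = delta_grid()
    if len(condition_trains) < 2 or len(null_trains) < 2:
        raise ValueError("need at least two trains per class")
    ref = np.asarray(reference_signal)
    scores, labels = [], []
    for trains, lab in ((condition_trains, 1), (null_trains, 0)):
        for sig in trains:
            sig = np.asarray(sig)
            if sig.shape != ref.shape:
                raise ValueError("all signals must match the reference length")
            scores.append(score_fn(ref, sig, grid))
            labels.append(np.full(len(grid), lab))
    return roc_auc(np.concatenate(scores), np.concatenate(labels))
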