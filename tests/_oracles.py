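"""Independent oracles shared between the unit and acceptance suites."""
import numpy as np
from scipy import stats


def pairwise_auc_oracle(scores, labels) -> float:
    """Brute-force Mann-Whitney: enumerate every positive-negative pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def dense_grid_best_product(scores, labels, step: float = 1e-4) -> float:
    """Best sensitivity x specificity over a dense threshold grid
    (vectorized; independent of the candidate-midpoint search)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    grid = np.arange(0.0, 1.0 + step / 2, step)
    pred = scores[None, :] > grid[:, None]
    pos = labels == 1
    neg = ~pos
    tp = pred[:, pos].sum(axis=1)
    fn = pos.sum() - tp
    fp = pred[:, neg].sum(axis=1)
    tn = neg.sum() - fp
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return float(np.max(sens * spec))


def binomial_99_interval(n: int, p: float):
    """Exact central 99% interval for a Binomial(n, p) count."""
    return stats.binom.ppf(0.005, n, p), stats.binom.ppf(0.995, n, p)
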