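"""Independent brute-force oracles used to cross-check the estimators.

These deliberately share no code with the package: the logistic oracle
is a shrinking grid search over (intercept, slope), the AUC oracle an
explicit loop over positive/negative pairs.
"""

from __future__ import annotations

import numpy as np


def bernoulli_loglik(x: np.ndarray, y: np.ndarray, intercept: float, slope: float) -> float:
    eta = intercept + slope * x
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def grid_logistic_oracle(
    x, y, span: float = 10.0, steps: int = 81, max_rounds: int = 80
) -> tuple[float, float]:
    """Maximise the Bernoulli log-likelihood by iterated grid refinement.

    Each round evaluates the log-likelihood on a steps x steps grid
    centred on the current best point.  If the argmax lands on a grid
    edge the box is doubled (the optimum lies outside); otherwise the
    box shrinks to a few grid spacings around the argmax.  Concavity of
    the log-likelihood makes the recentred shrinking box track the
    optimum; iteration stops once the spacing resolves 1e-5.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    center = (0.0, 0.0)
    width = span
    for _ in range(max_rounds):
        b0s = np.linspace(center[0] - width, center[0] + width, steps)
        b1s = np.linspace(center[1] - width, center[1] + width, steps)
        eta = b0s[:, None, None] + b1s[None, :, None] * x[None, None, :]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        center = (float(b0s[i]), float(b1s[j]))
        if i in (0, steps - 1) or j in (0, steps - 1):
            width *= 2.0  # optimum outside the box: expand
            continue
        spacing = 2.0 * width / (steps - 1)
        if spacing < 1e-5:
            break
        width = 4.0 * spacing
    return center


def pair_counting_auc(scores, labels) -> float:
    """AUC as (concordant + 0.5 * tied) / (n_pos * n_neg), by explicit loops."""
    scores = list(scores)
    labels = list(labels)
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def is_separable(x, y) -> bool:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = x[y == 1], x[y == 0]
    return bool(pos.min() >= neg.max() or pos.max() <= neg.min())
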