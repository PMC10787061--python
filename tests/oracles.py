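"""Independent slow oracles used to validate the fast implementations.

These deliberately share no code with the package internals they check.
"""

import numpy as np


def brute_force_auc(scores, labels) -> float:
    """Concordant-pair fraction over all case/control pairs (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    assert len(classes) == 2
    pos = scores[y == classes[-1]]
    neg = scores[y == classes[0]]
    total = concordant = 0.0
    for p in pos:
        for n in neg:
            total += 1
            if p > n:
                concordant += 1
            elif p == n:
                concordant += 0.5
    return concordant / total


def projected_gradient_l1_logistic(X, y01, lam, iters=50_000):
    """L1-logistic objective minimized by projected gradient on the split
    w = a - b with a, b >= 0 (features standardized, intercept unpenalized).

    Returns the achieved objective value
    (1/n) sum log(1+exp(z)) - y*z + lam*||w||_1 on the standardized scale.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    n, p = X.shape
    mean, sd = X.mean(0), X.std(0)
    sd[sd == 0] = 1.0
    Xs = (X - mean) / sd
    a = np.zeros(p)
    b = np.zeros(p)
    c = 0.0
    aug = np.hstack([Xs, np.ones((n, 1))])
    L = np.linalg.norm(aug, 2) ** 2 / (4 * n)
    step = 1.0 / L
    for _ in range(iters):
        z = Xs @ (a - b) + c
        s = 1.0 / (1.0 + np.exp(-z))
        r = s - y01
        g = Xs.T @ r / n
        a = np.maximum(a - step * (g + lam), 0.0)
        b = np.maximum(b - step * (-g + lam), 0.0)
        c -= step * r.mean()
    w = a - b
    z = Xs @ w + c
    nll = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y01 * z)
    return float(nll + lam * np.abs(w).sum())


def normal_power_two_sample(d: float, n: int, alpha: float = 0.05) -> float:
    """Closed-form normal-approximation power of the two-sided two-sample test."""
    from scipy.stats import norm

    z = norm.ppf(1 - alpha / 2)
    shift = d / np.sqrt(2.0 / n)
    return float(norm.cdf(shift - z) + norm.cdf(-shift - z))
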