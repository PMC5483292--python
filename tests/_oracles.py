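"""Independent brute-force oracles used to cross-check the statistics stage.

Deliberately written from first principles (no shared code with the package
implementation): Hotelling's T-squared from the pooled covariance, and its
exact F transform for two groups.
"""

import numpy as np


def hotelling_t2_f(X: np.ndarray, y: np.ndarray):
    """Two-sample Hotelling T² and its exact F statistic.

    T² = (n1 n2 / N) d' S⁻¹ d with S the pooled within-group covariance and
    d the mean difference; F = (N - k - 1) / ((N - 2) k) * T² on
    (k, N - k - 1) degrees of freedom.
    """
    groups = sorted(set(y.tolist()))
    assert len(groups) == 2
    X1, X2 = X[y == groups[0]], X[y == groups[1]]
    n1, n2 = len(X1), len(X2)
    k = X.shape[1]
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S = ((X1 - X1.mean(0)).T @ (X1 - X1.mean(0)) + (X2 - X2.mean(0)).T @ (X2 - X2.mean(0))) / (
        n1 + n2 - 2
    )
    t2 = n1 * n2 / (n1 + n2) * d @ np.linalg.solve(S, d)
    f = (n1 + n2 - k - 1) / ((n1 + n2 - 2) * k) * t2
    return float(t2), float(f), (k, n1 + n2 - k - 1)


def pooled_t_squared(x: np.ndarray, y: np.ndarray):
    """Squared two-sample pooled-variance t statistic (univariate)."""
    groups = sorted(set(y.tolist()))
    a, b = x[y == groups[0]], x[y == groups[1]]
    n1, n2 = len(a), len(b)
    sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return float(t**2)
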