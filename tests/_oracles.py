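"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the max-margin oracle
is an exhaustive direction search (exact for separable 2-D data up to the
angular grid), the Platt oracle is a derivative-free likelihood search,
and the BH oracle is a literal transcription of the step-up definition.
"""

import numpy as np
from scipy.optimize import minimize, minimize_scalar


def max_margin_oracle(points, labels):
    """Maximum-margin separator of separable 2-D data by direction search.

    For a fixed unit normal u the best offset centers the slab between the
    two classes, giving margin(u) = (min_+ u.x - max_- u.x) / 2; the
    separator maximizes this over u on the half-circle.  Returns
    (margin, slope, intercept) of the line in the (AD, RD) plane.
    """
    X = np.asarray(points, dtype=float)
    y = np.asarray(labels)
    pos = X[y == 1]
    neg = X[y == 0]

    def margin_of(theta):
        u = np.array([np.cos(theta), np.sin(theta)])
        return (np.min(pos @ u) - np.max(neg @ u)) / 2.0

    # full circle: margin_of is orientation-dependent, so both signs of the
    # normal must be explored; separable data has a positive maximum
    thetas = np.linspace(0.0, 2 * np.pi, 40001)
    vals = np.array([margin_of(t) for t in thetas])
    best = int(np.argmax(vals))
    t0 = thetas[best]
    res = minimize_scalar(
        lambda t: -margin_of(t),
        bracket=(t0 - 2e-4, t0, t0 + 2e-4),
        method="brent", options={"xtol": 1e-14},
    )
    theta = res.x
    margin = margin_of(theta)
    u = np.array([np.cos(theta), np.sin(theta)])
    offset = -(np.min(pos @ u) + np.max(neg @ u)) / 2.0
    # line u . x + offset = 0  ->  RD = -(u0/u1) AD - offset/u1
    slope = -u[0] / u[1]
    intercept = -offset / u[1]
    return margin, slope, intercept


def platt_objective(A, B, f, t):
    z = A * np.asarray(f) + B
    return float(np.sum(np.where(
        z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1) * z + np.log1p(np.exp(z))
    )))


def platt_oracle(decision_values, y, span=20.0):
    """Brute-force fit of the smoothed-target sigmoid: coarse grid over
    (A, B) followed by a derivative-free simplex polish."""
    f = np.asarray(decision_values, dtype=float)
    y = np.asarray(y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    t = np.where(y == 1, (n_pos + 1.0) / (n_pos + 2.0), 1.0 / (n_neg + 2.0))
    grid = np.linspace(-span, span, 161)
    best, best_val = (0.0, 0.0), np.inf
    for A in grid:
        for B in grid:
            val = platt_objective(A, B, f, t)
            if val < best_val:
                best, best_val = (A, B), val
    res = minimize(
        lambda ab: platt_objective(ab[0], ab[1], f, t),
        np.array(best), method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000},
    )
    return float(res.x[0]), float(res.x[1])


def bh_oracle(pvalues):
    """Literal step-up definition: adjusted_(i) = min_{j>=i} p_(j)*m/j."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adjusted_sorted = np.empty(m)
    for i in range(m):
        adjusted_sorted[i] = min(
            min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0
        )
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
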