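"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own code paths (and sklearn's
fitted estimators): plain-Python recursive CART with exhaustive split
search, and a penalized logistic likelihood minimized directly with
scipy. They exist only to serve as oracles in tests.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

_TOL = 1e-12


def gini_node_cost(y) -> float:
    n = len(y)
    if n == 0:
        return 0.0
    return n - sum(c * c for c in Counter(y).values()) / n


def sse_node_cost(y) -> float:
    if len(y) == 0:
        return 0.0
    mean = sum(y) / len(y)
    return sum((v - mean) ** 2 for v in y)


def brute_force_cart(
    presence: list[list[bool]],
    y: list,
    feature_names: list[str],
    max_depth: int,
    min_samples_leaf: int = 1,
    task: str = "classification",
):
    """Exhaustive-search CART as a nested dict, lexicographic tie-break."""
    cost = gini_node_cost if task == "classification" else sse_node_cost
    order = sorted(range(len(feature_names)), key=lambda j: feature_names[j])

    def leaf(idx):
        values = [y[i] for i in idx]
        if task == "regression":
            return {"leaf": sum(values) / len(values), "n": len(idx)}
        classes = sorted(set(y))
        freq = [sum(1 for v in values if v == c) / len(values) for c in classes]
        return {"leaf": freq, "n": len(idx)}

    def grow(idx, depth):
        values = [y[i] for i in idx]
        parent = cost(values)
        if depth >= max_depth or parent <= 0.0 or len(idx) < 2 * min_samples_leaf:
            return leaf(idx)
        best = None
        for j in order:
            left = [i for i in idx if presence[i][j]]
            right = [i for i in idx if not presence[i][j]]
            if not left or not right:
                continue
            delta = parent - cost([y[i] for i in left]) - cost([y[i] for i in right])
            if best is None or delta > best[0] + _TOL:
                best = (delta, j, left, right)
        if best is None or best[0] <= _TOL:
            return leaf(idx)
        delta, j, left, right = best
        if len(left) < min_samples_leaf or len(right) < min_samples_leaf:
            return leaf(idx)
        node = leaf(idx)
        node.update(
            {
                "feature": feature_names[j],
                "delta": delta,
                "left": grow(left, depth + 1),
                "right": grow(right, depth + 1),
            }
        )
        return node

    return grow(list(range(len(y))), 0)


def predict_brute_force(node, presence_row: dict[str, bool]):
    while "feature" in node:
        node = node["left"] if presence_row.get(node["feature"], False) else node["right"]
    return node["leaf"]


def l2_logistic_oracle(X: np.ndarray, y01: np.ndarray, lam: float):
    """Minimize sum cross-entropy + lam/2 ||w||^2 (intercept unpenalized).

    Matches a scikit-learn ``LogisticRegression(C=1/lam)`` objective but
    is solved directly on the explicit count matrix.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    d = X.shape[1]

    def objective(params):
        w, b = params[:d], params[d]
        z = X @ w + b
        loss = np.sum(np.logaddexp(0.0, z) - y01 * z)
        return loss + 0.5 * lam * w @ w

    def gradient(params):
        w, b = params[:d], params[d]
        p = expit(X @ w + b)
        return np.append(X.T @ (p - y01) + lam * w, np.sum(p - y01))

    result = minimize(
        objective,
        np.zeros(d + 1),
        jac=gradient,
        method="L-BFGS-B",
        options={"maxiter": 10000, "ftol": 1e-16, "gtol": 1e-10},
    )
    return result.x[:d], float(result.x[d])
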