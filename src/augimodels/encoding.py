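"""Voxelwise encoding models: lagged word-window features -> ridge -> correlation.

Continuous responses (e.g. per-voxel fMRI time courses) are predicted
from the text heard before each acquisition time. For a timepoint with
word offset ``m`` (the number of words observed so far), the most
recent ``delay`` words are skipped to account for response lag, and the
``window`` words before those form the feature window:

    words  [max(1, m - delay - window + 1) .. m - delay]   (1-based)

The window text is featurized by any document featurizer (here, summed
ngram embeddings), one ridge regression is fit per response target with
the penalty chosen by cross-validation (sharing the design-matrix SVD
across targets), and test-set Pearson correlations are summarized over
all targets and over the top 1% / 5% best-predicted targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "WindowConfig",
    "RidgeEncoders",
    "VoxelScores",
    "window_indices",
    "window_features",
    "build_design_matrix",
    "fit_ridge_encoders",
    "score_voxels",
]


@dataclass(frozen=True)
class WindowConfig:
    """Lagged feature window: ``window`` words, skipping the ``delay`` most recent."""

    window: int = 20
    delay: int = 4

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.delay < 0:
            raise ValueError("delay must be >= 0")


def window_indices(m: int, config: WindowConfig) -> tuple[int, int]:
    """Half-open 0-based slice ``[start, stop)`` of the window for offset ``m``.

    Equivalent to 1-based inclusive indices
    ``max(1, m - delay - window + 1) .. m - delay``; empty when fewer
    than ``delay + 1`` words have been observed.
    """
    stop = max(0, m - config.delay)
    start = max(0, stop - config.window)
    return start, stop


def window_features(
    words: Sequence[str],
    offsets: Sequence[int],
    t: int,
    config: WindowConfig,
    featurizer: Callable[[str], np.ndarray],
) -> np.ndarray:
    """Featurize the lagged window preceding timepoint ``t``.

    ``featurizer`` maps window text to a vector (typically summed ngram
    embeddings). Truncated windows use whatever words are available; an
    empty window yields the zero vector (the featurizer is probed on an
    empty string to learn the dimension).
    """
    if not 0 <= t < len(offsets):
        raise IndexError(f"timepoint {t} outside dataset of {len(offsets)}")
    start, stop = window_indices(int(offsets[t]), config)
    return np.asarray(featurizer(" ".join(words[start:stop])), dtype=float)


def build_design_matrix(
    words: Sequence[str],
    offsets: Sequence[int],
    config: WindowConfig,
    featurizer: Callable[[str], np.ndarray],
) -> np.ndarray:
    offsets = np.asarray(offsets)
    if np.any(np.diff(offsets) < 0):
        raise ValueError("word offsets must be non-decreasing")
    rows = [
        window_features(words, offsets, t, config, featurizer)
        for t in range(len(offsets))
    ]
    return np.vstack(rows)


# ---------------------------------------------------------------------------
# ridge


@dataclass
class RidgeEncoders:
    """Per-target ridge weights on centered features.

    Prediction is ``(X - x_mean) @ weights + y_mean`` with each target's
    own selected penalty.
    """

    weights: np.ndarray  # (n_features, n_targets)
    x_mean: np.ndarray
    y_mean: np.ndarray
    alphas: np.ndarray  # chosen penalty per target
    cv_mse: np.ndarray  # (n_alphas, n_targets)
    alpha_grid: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X) - self.x_mean) @ self.weights + self.y_mean


def _ridge_coefs_svd(U, s, Vt, Yc: np.ndarray, alpha: float) -> np.ndarray:
    # w = V diag(s / (s^2 + alpha)) U^T Yc, for all targets at once
    shrink = s / (s**2 + alpha)
    return Vt.T @ (shrink[:, None] * (U.T @ Yc))


def fit_ridge_encoders(
    X: np.ndarray,
    Y: np.ndarray,
    alphas: Sequence[float] = (0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
    cv_folds: int = 5,
    seed: int = 0,
) -> RidgeEncoders:
    """Closed-form ridge per target, penalty selected by cross-validation.

    One SVD of the (centered) training design is shared across all
    targets and penalties per fold, so the cost is dominated by a single
    decomposition rather than the number of voxels. A zero penalty on a
    rank-deficient design is rejected with a pointer to use ``alpha > 0``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    alphas = np.asarray(sorted(alphas), dtype=float)
    if np.any(alphas < 0):
        raise ValueError("penalties must be >= 0")
    if 0.0 in alphas:
        if np.linalg.matrix_rank(X - X.mean(axis=0)) < min(X.shape[0] - 1, X.shape[1]):
            raise ValueError(
                "design matrix is rank-deficient; a zero ridge penalty is "
                "ill-posed — use alpha > 0"
            )

    n_targets = Y.shape[1]
    cv_sse = np.zeros((len(alphas), n_targets))
    if len(alphas) > 1:
        splitter = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        for train_idx, val_idx in splitter.split(X):
            x_mean = X[train_idx].mean(axis=0)
            y_mean = Y[train_idx].mean(axis=0)
            Xc = X[train_idx] - x_mean
            Yc = Y[train_idx] - y_mean
            U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
            Xv = X[val_idx] - x_mean
            for a, alpha in enumerate(alphas):
                W = _ridge_coefs_svd(U, s, Vt, Yc, alpha)
                resid = Xv @ W + y_mean - Y[val_idx]
                cv_sse[a] += np.sum(resid**2, axis=0)
    chosen_idx = np.argmin(cv_sse, axis=0)  # first minimizer: smaller alpha wins ties
    cv_mse = cv_sse / X.shape[0]

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    weights = np.empty((X.shape[1], n_targets))
    for a, alpha in enumerate(alphas):
        cols = np.flatnonzero(chosen_idx == a)
        if cols.size:
            weights[:, cols] = _ridge_coefs_svd(U, s, Vt, Yc[:, cols], alpha)
    return RidgeEncoders(
        weights=weights,
        x_mean=x_mean,
        y_mean=y_mean,
        alphas=alphas[chosen_idx],
        cv_mse=cv_mse,
        alpha_grid=alphas,
    )


# ---------------------------------------------------------------------------
# scoring


@dataclass
class VoxelScores:
    """Per-target test correlations and top-fraction summaries."""

    r: np.ndarray
    zero_variance: np.ndarray  # targets whose actual/predicted variance vanished
    mean_r: float
    top_means: dict[float, float]  # fraction -> mean r over best targets

    def to_tsv(self, path, target_names: Sequence[str] | None = None):
        from pathlib import Path

        path = Path(path)
        names = target_names or [f"target_{i}" for i in range(len(self.r))]
        with path.open("w") as fh:
            fh.write("target\tr\tzero_variance\n")
            for name, r, flag in zip(names, self.r, self.zero_variance):
                fh.write(f"{name}\t{repr(float(r))}\t{int(flag)}\n")
        return path


def score_voxels(
    predicted: np.ndarray,
    actual: np.ndarray,
    top_fractions: Sequence[float] = (0.01, 0.05),
) -> VoxelScores:
    """Pearson r per target plus means over all and over the best targets.

    Targets whose predicted or actual series has zero variance get
    ``r = 0`` and are flagged. "Top f" means the ``max(1, round(f * n))``
    targets with the highest test correlation; by construction the top-1%
    mean >= top-5% mean >= overall mean.
    """
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.ndim == 1:
        predicted = predicted[:, None]
    if actual.ndim == 1:
        actual = actual[:, None]
    if predicted.shape != actual.shape:
        raise ValueError("predicted and actual must have the same shape")
    pc = predicted - predicted.mean(axis=0)
    ac = actual - actual.mean(axis=0)
    p_sd = np.sqrt(np.sum(pc**2, axis=0))
    a_sd = np.sqrt(np.sum(ac**2, axis=0))
    zero_var = (p_sd == 0) | (a_sd == 0)
    denom = np.where(zero_var, 1.0, p_sd * a_sd)
    r = np.where(zero_var, 0.0, np.sum(pc * ac, axis=0) / denom)

    n = len(r)
    ranked = np.sort(r)[::-1]
    top_means = {}
    for frac in top_fractions:
        k = max(1, int(round(frac * n)))
        top_means[float(frac)] = float(np.mean(ranked[:k]))
    return VoxelScores(
        r=r,
        zero_variance=zero_var,
        mean_r=float(np.mean(r)),
        top_means=top_means,
    )
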