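"""Motion-state recognition with a generalized regression neural network.

The GRNN is lazy kernel regression (Nadaraya-Watson with a Gaussian
kernel): training stores the feature rows and their numeric state targets;
a prediction is the kernel-weighted average of the stored targets,

.. math::

   \\hat y(x) = \\frac{\\sum_i w_i y_i}{\\sum_i w_i},\\qquad
   w_i = \\exp\\!\\left(-\\frac{\\lVert x - x_i\\rVert^2}{2\\sigma^2}\\right),

with a single isotropic smoothing parameter sigma.  Features are
standardized per column before distances are taken, because the variance
column lives on a very different scale from the extrema columns.

States are encoded numerically: 1 = acceleration, -1 = deceleration,
0 = static.  Predictions are decoded to the nearest label, with exact
midpoints (+-0.5) rounding toward 0 -- the grasp-safe choice, since a
spurious static call can at worst trigger one command while a spurious
motion call suppresses one.

Sigma is chosen by k-fold cross-validation (10 folds by default) over a
grid, minimizing the mean held-out MSE of the raw regression outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .signal_processing import window_variance

#: Numeric state labels: acceleration, deceleration, static.
STATE_ACCELERATION = 1
STATE_DECELERATION = -1
STATE_STATIC = 0
STATE_LABELS = (STATE_ACCELERATION, STATE_DECELERATION, STATE_STATIC)

#: Column names of a state feature row, in order.
FEATURE_COLUMNS = ("var", "diff", "emax", "emin")

#: Default sigma grid for cross-validation: 0.1 .. 2.0 step 0.1.
DEFAULT_SIGMA_GRID = tuple(np.round(np.arange(0.1, 2.01, 0.1), 10))

_MODEL_SCHEMA_VERSION = 1


def state_features(e_values: Iterable[float]) -> np.ndarray:
    """The 4-column feature row of one window's E series.

    ``[VAR, E_N - E_1, max(E), min(E)]`` -- the net change telescopes the
    successive differences, so its sign separates acceleration (positive)
    from deceleration (negative).
    """
    e = np.asarray(e_values, dtype=float)
    if e.size < 2:
        raise ValueError("state features need at least 2 E values")
    return np.array([
        window_variance(e),
        float(e[-1] - e[0]),
        float(np.max(e)),
        float(np.min(e)),
    ])


@dataclass
class GrnnModel:
    """Stored (scaled) training rows, targets, scaling, and sigma."""

    features_scaled: np.ndarray
    targets: np.ndarray
    sigma: float
    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.features_scaled.ndim != 2 or self.features_scaled.shape[0] < 1:
            raise ValueError("model needs at least one training row")
        if self.targets.shape[0] != self.features_scaled.shape[0]:
            raise ValueError("features and targets must have the same count")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def n_train(self) -> int:
        return self.features_scaled.shape[0]

    # -- persistence -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": _MODEL_SCHEMA_VERSION,
            "sigma": float(self.sigma),
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "features_scaled": self.features_scaled.tolist(),
            "targets": self.targets.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "GrnnModel":
        return cls(
            features_scaled=np.asarray(payload["features_scaled"], dtype=float),
            targets=np.asarray(payload["targets"], dtype=float),
            sigma=float(payload["sigma"]),
            center=np.asarray(payload["center"], dtype=float),
            scale=np.asarray(payload["scale"], dtype=float),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "GrnnModel":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))


def train_state_model(features, targets, sigma: float) -> GrnnModel:
    """Store standardized features, raw targets and sigma (lazy training)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] < 1 or X.shape[0] != y.shape[0]:
        raise ValueError("need equally many (>= 1) feature rows and targets")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant columns stay centered
    return GrnnModel(
        features_scaled=(X - center) / scale,
        targets=y,
        sigma=float(sigma),
        center=center,
        scale=scale,
    )


def grnn_predict(model: GrnnModel, rows) -> float | np.ndarray:
    """Kernel-regression output for one row (scalar) or a matrix of rows.

    The output is a convex combination of the stored targets; if every
    kernel weight underflows to zero the nearest stored row's target is
    returned instead.
    """
    X = np.asarray(rows, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature rows must be finite")
    Xs = (X - model.center) / model.scale
    # squared Euclidean distances, (n_query, n_train)
    d2 = (
        np.sum(Xs * Xs, axis=1)[:, None]
        + np.sum(model.features_scaled * model.features_scaled, axis=1)[None, :]
        - 2.0 * Xs @ model.features_scaled.T
    )
    np.maximum(d2, 0.0, out=d2)
    # subtracting the row-min keeps the weights from all underflowing and
    # leaves the weighted average unchanged
    d2min = d2.min(axis=1, keepdims=True)
    w = np.exp(-(d2 - d2min) / (2.0 * model.sigma**2))
    sw = w.sum(axis=1)
    yhat = np.empty(X.shape[0])
    ok = sw > 0
    yhat[ok] = (w[ok] @ model.targets) / sw[ok]
    if np.any(~ok):  # pragma: no cover - shift makes underflow unreachable
        yhat[~ok] = model.targets[np.argmin(d2[~ok], axis=1)]
    return float(yhat[0]) if single else yhat


def decode_state(yhat) -> int | np.ndarray:
    """Nearest label in {-1, 0, 1}; midpoints (+-0.5) round toward 0."""
    y = np.asarray(yhat, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("prediction must be finite")
    out = np.where(y > 0.5, 1, np.where(y < -0.5, -1, 0))
    return int(out) if y.ndim == 0 else out.astype(int)


@dataclass(frozen=True)
class CvResult:
    """Cross-validation summary for the sigma grid."""

    sigma_grid: np.ndarray
    mse_per_sigma: np.ndarray
    selected_sigma: float
    fold_seed: int
    folds: int

    def to_dict(self) -> dict:
        return {
            "sigma_grid": self.sigma_grid.tolist(),
            "mse_per_sigma": self.mse_per_sigma.tolist(),
            "selected_sigma": float(self.selected_sigma),
            "fold_seed": int(self.fold_seed),
            "folds": int(self.folds),
        }


def fold_indices(n: int, folds: int, seed: int) -> list[np.ndarray]:
    """Seeded even partition of ``range(n)`` into ``folds`` test folds.

    A seeded random permutation is split into ``folds`` contiguous chunks
    whose sizes differ by at most one; every sample lands in exactly one
    test fold.
    """
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    perm = np.random.default_rng(seed).permutation(n)
    return list(np.array_split(perm, folds))


def cross_validate_sigma(
    features,
    targets,
    sigma_grid: Iterable[float] = DEFAULT_SIGMA_GRID,
    folds: int = 10,
    seed: int = 0,
) -> CvResult:
    """Select sigma by k-fold CV, minimizing mean held-out MSE.

    The MSE is computed on the raw regression outputs (not decoded
    labels).  Ties select the smallest sigma.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(targets, dtype=float).ravel()
    grid = np.asarray(list(sigma_grid), dtype=float)
    if grid.size == 0 or np.any(grid <= 0):
        raise ValueError("sigma grid must be non-empty with all sigma > 0")
    test_folds = fold_indices(X.shape[0], folds, seed)
    all_idx = np.arange(X.shape[0])
    mse = np.zeros(grid.size)
    for k, sigma in enumerate(grid):
        fold_mses = []
        for test_idx in test_folds:
            train_mask = np.ones(X.shape[0], dtype=bool)
            train_mask[test_idx] = False
            model = train_state_model(X[train_mask], y[train_mask], sigma)
            pred = grnn_predict(model, X[test_idx])
            fold_mses.append(float(np.mean((pred - y[test_idx]) ** 2)))
        mse[k] = np.mean(fold_mses)
    best = np.min(mse)
    candidates = grid[mse == best]
    selected = float(np.min(candidates))
    return CvResult(
        sigma_grid=grid,
        mse_per_sigma=mse,
        selected_sigma=selected,
        fold_seed=seed,
        folds=folds,
    )
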