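"""Dimer-rise collective mode by one-component PLS regression.

Functional mode analysis: regress high-dimensional (backbone-like) feature
trajectories against the axial box dimension L_z with exactly one partial
least squares component, giving the ensemble-weighted collective mode that
correlates best with axial lattice spacing. Generalization is assessed by
split-half cross-validation on a held-out trajectory segment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.cross_decomposition import PLSRegression

from .lattice import FeatureTrajectory

__all__ = ["CollectiveMode", "fit_pls_mode", "project"]


class DegenerateFitError(ValueError):
    """Raised when the regression target has no variance."""


@dataclass
class CollectiveMode:
    """A fitted one-component PLS mode.

    ``weights`` is the unit-norm direction in feature space; projections
    are calibrated to nm by an affine map (``slope``, ``intercept``) fitted
    against the training target. ``r_train``/``r_valid`` are Pearson
    correlations of the projection with the target on the two halves.
    """

    weights: np.ndarray
    x_mean: np.ndarray
    slope: float
    intercept: float
    r_train: float
    r_valid: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "weights": self.weights.tolist(),
            "x_mean": self.x_mean.tolist(),
            "slope": self.slope,
            "intercept": self.intercept,
            "r_train": self.r_train,
            "r_valid": self.r_valid,
        }, indent=1))

    @classmethod
    def from_json(cls, path) -> "CollectiveMode":
        d = json.loads(Path(path).read_text())
        return cls(weights=np.asarray(d["weights"]),
                   x_mean=np.asarray(d["x_mean"]),
                   slope=d["slope"], intercept=d["intercept"],
                   r_train=d["r_train"], r_valid=d["r_valid"])


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def fit_pls_mode(train: FeatureTrajectory, valid: FeatureTrajectory, *,
                 scale: bool = False) -> CollectiveMode:
    """Fit the one-component PLS collective mode on ``train``.

    Features are mean-centered; variance scaling is off by default since
    coordinate features share units (enable with ``scale=True``).
    """
    if train.X.shape[1] != valid.X.shape[1]:
        raise ValueError("train and valid must share feature dimensionality")
    if train.X.shape[0] < 10 or valid.X.shape[0] < 10:
        raise ValueError("need at least 10 frames per half")
    if np.ptp(train.y) == 0:
        raise DegenerateFitError("training target is constant")

    pls = PLSRegression(n_components=1, scale=scale)
    pls.fit(train.X, train.y)
    w = pls.x_rotations_[:, 0]
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise DegenerateFitError("PLS produced a null direction")
    w = w / nrm
    x_mean = train.X.mean(axis=0)

    score = (train.X - x_mean) @ w
    if score.std() == 0:
        raise DegenerateFitError("projection has no variance on training data")
    # affine calibration of the score to nm against the training target
    slope, intercept = np.polyfit(score, train.y, 1)

    proj_train = score * slope + intercept
    proj_valid = ((valid.X - x_mean) @ w) * slope + intercept
    return CollectiveMode(
        weights=w, x_mean=x_mean, slope=float(slope), intercept=float(intercept),
        r_train=_corr(proj_train, train.y), r_valid=_corr(proj_valid, valid.y))


def project(traj: FeatureTrajectory, mode: CollectiveMode) -> np.ndarray:
    """Project each frame onto the mode, calibrated to nm."""
    if traj.X.shape[1] != mode.weights.shape[0]:
        raise ValueError("feature dimensionality does not match the mode")
    return ((traj.X - mode.x_mean) @ mode.weights) * mode.slope + mode.intercept
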