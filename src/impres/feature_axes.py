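"""Feature axes overlaid on an unfolding solution, and projection scores.

A *feature axis* is the direction in the map that maximally separates the
two levels of a categorical stimulus feature (race, age, ...). It is fitted
by bias-reduced (Firth) logistic regression of the feature labels on the
stimulus coordinates: the Jeffreys-prior penalty keeps the estimates finite
even when the levels are completely separated in the map — the typical case
for a well-recovered feature, where ordinary maximum likelihood diverges.
Continuous stimulus features (e.g. rated trustworthiness) get an axis from
ordinary least squares instead, with R² as the fit diagnostic.

The cosine of the angle between two axes reflects the correlation between
the corresponding preference dimensions. Participant preference scores on an
axis are obtained by orthogonally projecting the participant points onto it,
after centering at the participant centroid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import expit

from .errors import InvalidInputError, NumericalError
from .unfolding import UnfoldingSolution

__all__ = [
    "FeatureAxis",
    "firth_logistic",
    "fit_categorical_axis",
    "fit_continuous_axis",
    "axis_cosine",
    "project_points",
    "flag_extreme_points",
]


@dataclass(frozen=True)
class FeatureAxis:
    feature: str
    positive_level: Optional[str]  # None for continuous features
    direction: np.ndarray  # unit vector, length d
    intercept: float
    fit_kind: str  # "bias_reduced_logistic" | "linear"
    goodness: float  # side-of-boundary accuracy, or R^2

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if not np.isfinite(norm) or norm == 0:
            raise InvalidInputError("axis direction must be a finite nonzero vector")
        object.__setattr__(self, "direction", d / norm)


def firth_logistic(
    design: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> np.ndarray:
    """Bias-reduced logistic regression (Firth penalized likelihood).

    Maximizes ``loglik(beta) + 0.5 * logdet(Fisher info)`` by iteratively
    reweighted least squares with the hat-diagonal score adjustment
    ``X' (y - p + h (1/2 - p))``. The design matrix must include its own
    intercept column. Estimates are finite even under complete separation.
    """
    x = np.asarray(design, dtype=float)
    y = np.asarray(labels, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise InvalidInputError("design and labels have incompatible shapes")
    m, p = x.shape
    if m < p:
        raise InvalidInputError(f"need at least {p} observations, got {m}")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise InvalidInputError("labels must be binary 0/1")

    def penalized_loglik(beta: np.ndarray) -> float:
        eta = x @ beta
        ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        pr = expit(eta)
        wdiag = pr * (1.0 - pr)
        info = (x * wdiag[:, None]).T @ x
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        return ll + 0.5 * logdet

    beta = np.zeros(p)
    ll_old = penalized_loglik(beta)
    grad_norm = np.inf
    for _ in range(max_iter):
        eta = x @ beta
        pr = expit(eta)
        wdiag = pr * (1.0 - pr)
        info = (x * wdiag[:, None]).T @ x
        # pinv: a rank-deficient design (e.g. a constant coordinate) yields
        # the minimum-norm step, leaving redundant directions at zero
        info_inv = np.linalg.pinv(info)
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        h = np.einsum("ij,jk,ik->i", x, info_inv, x) * wdiag
        score = x.T @ (y - pr + h * (0.5 - pr))
        grad_norm = float(np.linalg.norm(score))
        step = info_inv @ score
        # step-halving keeps the penalized likelihood ascending
        for _ in range(30):
            beta_new = beta + step
            ll_new = penalized_loglik(beta_new)
            if ll_new >= ll_old - 1e-12:
                break
            step = step / 2.0
        else:
            beta_new, ll_new = beta, ll_old
        delta = float(np.linalg.norm(beta_new - beta))
        beta, ll_old = beta_new, ll_new
        if delta < tol:
            return beta
    raise NumericalError(
        f"Firth logistic regression did not converge in {max_iter} iterations "
        f"(last gradient norm {grad_norm:.3e})"
    )


def fit_categorical_axis(
    solution: UnfoldingSolution,
    labels: Sequence[str],
    feature: str,
    positive_level: str,
) -> FeatureAxis:
    """Maximally separating axis for a two-level stimulus feature.

    The labels are regressed on the stimulus coordinates by Firth logistic
    regression; the axis direction is the normalized slope vector, oriented
    toward ``positive_level``. Goodness is the fraction of stimuli on the
    correct side of the implied boundary.
    """
    labels = np.asarray(labels)
    coords = solution.col_coords
    if labels.shape[0] != coords.shape[0]:
        raise InvalidInputError("one label per stimulus required")
    y = (labels == positive_level).astype(float)
    if y.all() or not y.any():
        raise InvalidInputError(
            f"feature {feature!r} has a single level among these stimuli"
        )
    design = np.hstack([np.ones((coords.shape[0], 1)), coords])
    beta = firth_logistic(design, y)
    slope = beta[1:]
    if np.linalg.norm(slope) == 0:
        raise NumericalError("zero slope vector; feature carries no direction")
    predicted = (design @ beta) > 0
    accuracy = float(np.mean(predicted == (y == 1.0)))
    return FeatureAxis(
        feature=feature,
        positive_level=positive_level,
        direction=slope,
        intercept=float(beta[0]),
        fit_kind="bias_reduced_logistic",
        goodness=accuracy,
    )


def fit_continuous_axis(
    solution: UnfoldingSolution,
    values: Sequence[float],
    feature: str,
) -> FeatureAxis:
    """Axis for a continuous stimulus feature via OLS of the values on the
    stimulus coordinates; goodness is the regression R²."""
    values = np.asarray(values, dtype=float)
    coords = solution.col_coords
    if values.shape[0] != coords.shape[0]:
        raise InvalidInputError("one value per stimulus required")
    if coords.shape[0] < solution.ndim + 1:
        raise InvalidInputError("need at least ndim+1 stimuli")
    if np.ptp(values) == 0:
        raise InvalidInputError("constant feature values define no axis")
    design = np.hstack([np.ones((coords.shape[0], 1)), coords])
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    fitted = design @ beta
    ss_res = float(np.sum((values - fitted) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    slope = beta[1:]
    if np.linalg.norm(slope) == 0:
        raise NumericalError("zero slope vector; values unrelated to coordinates")
    return FeatureAxis(
        feature=feature,
        positive_level=None,
        direction=slope,
        intercept=float(beta[0]),
        fit_kind="linear",
        goodness=1.0 - ss_res / ss_tot,
    )


def axis_cosine(a: FeatureAxis, b: FeatureAxis) -> float:
    """Cosine of the angle between two axes — the correlation between the
    preference dimensions they represent. In [−1, 1]."""
    if a.direction.shape != b.direction.shape:
        raise InvalidInputError("axes live in different dimensionalities")
    return float(np.clip(a.direction @ b.direction, -1.0, 1.0))


def project_points(
    solution: UnfoldingSolution,
    axis: FeatureAxis,
    which: str = "participants",
) -> np.ndarray:
    """Orthogonal projections of points onto an axis, centered at the
    participant centroid; higher = closer to the positive-level side."""
    if axis.direction.shape[0] != solution.ndim:
        raise InvalidInputError("axis dimensionality does not match solution")
    pts = solution.row_coords if which == "participants" else solution.col_coords
    center = solution.row_coords.mean(axis=0)
    return (pts - center) @ axis.direction


def _spatial_median(points: np.ndarray, max_iter: int = 200, tol: float = 1e-10) -> np.ndarray:
    """Geometric (spatial) median by Weiszfeld iteration."""
    med = points.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(points - med, axis=1)
        if np.any(dist < 1e-12):  # median hits a data point
            return med
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - med) < tol:
            return new
        med = new
    return med


def flag_extreme_points(
    solution: UnfoldingSolution,
    which: str = "participants",
    k: float = 3.0,
) -> list[int]:
    """Indices of points lying unusually far from the point set's spatial
    median: flagged when the distance exceeds the median distance by more
    than ``k`` median absolute deviations (a modified z-score on distances,
    robust to the outliers being screened for).

    A screen for extreme responders; flagged points warrant inspection, not
    automatic exclusion.
    """
    pts = solution.row_coords if which == "participants" else solution.col_coords
    if pts.shape[0] < 5:
        raise InvalidInputError("need at least 5 points to flag outliers")
    med = _spatial_median(pts)
    dist = np.linalg.norm(pts - med, axis=1)
    mad = float(np.median(np.abs(dist - np.median(dist))))
    return [int(i) for i in np.nonzero(dist - np.median(dist) > k * mad)[0]]
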