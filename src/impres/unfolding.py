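"""Metric multidimensional unfolding by iterative stress majorization.

Unfolding embeds two point sets — ideal points for participants and
locations for stimuli — in a common d-dimensional space so that the
participant–stimulus distances approximate a rectangular dissimilarity
matrix: the smaller the distance, the stronger the preference. Preference
counts are converted to dissimilarities by linear reverse scoring,
``delta = K − count``, where K is the number of times each stimulus could
have been chosen.

The fit minimizes normalized stress-1,

    sigma_1 = sqrt( sum_ij w_ij (delta_ij − d_ij)^2 / sum_ij w_ij d_ij^2 ),

which lies on a 0–1 scale. The solver is SMACOF-style majorization
specialized to the rectangular case: only between-set (participant,
stimulus) pairs enter the loss, so the joint weight matrix has zero blocks
within each set. Each iteration applies the Guttman transform to the joint
configuration and then rescales the configuration by the optimal factor
``sum w*delta*d / sum w*d^2``; with that rescaling, stress-1 is a strictly
decreasing function of the (scale-optimal) raw stress the Guttman step
majorizes, so stress-1 is non-increasing at every iteration. The solver
asserts this and raises if it is ever violated.

Degenerate solutions (all points collapsing) are not penalized away; they
are surfaced via a diagnostic — the variance of the fitted distances over
the variance of the dissimilarities — on the returned solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import DegenerateDataError, InvalidInputError, NumericalError
from .scoring import PreferenceMatrix

__all__ = [
    "DissimilarityMatrix",
    "UnfoldingSolution",
    "counts_to_dissimilarities",
    "stress",
    "fit_unfolding",
    "select_dimensionality",
    "rotate_to_principal_axes",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Rectangular participants × stimuli dissimilarities with optional weights."""

    delta: np.ndarray
    weights: Optional[np.ndarray] = None
    row_ids: Optional[tuple] = None
    col_ids: Optional[tuple] = None

    def __post_init__(self) -> None:
        delta = np.asarray(self.delta, dtype=float)
        if delta.ndim != 2:
            raise InvalidInputError("delta must be 2-D (participants x stimuli)")
        if not np.all(np.isfinite(delta)):
            raise InvalidInputError("delta must be finite")
        if np.any(delta < 0):
            raise InvalidInputError("delta must be nonnegative")
        object.__setattr__(self, "delta", delta)
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if w.shape != delta.shape or np.any(w < 0) or not np.all(np.isfinite(w)):
                raise InvalidInputError("weights must match delta's shape and be >= 0")
            object.__setattr__(self, "weights", w)


@dataclass
class UnfoldingSolution:
    """A fitted unfolding map: joint coordinates, stress, and diagnostics."""

    row_coords: np.ndarray  # participants x d
    col_coords: np.ndarray  # stimuli x d
    ndim: int
    stress: float
    iterations: int
    converged: bool
    rng_seed: Optional[int] = None
    row_ids: Optional[tuple] = None
    col_ids: Optional[tuple] = None
    distance_variance_ratio: Optional[float] = None
    stress_history: Optional[list] = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-format coordinate table (point_id, point_type, dim1..dimd)."""
        nrow, d = self.row_coords.shape
        ncol = self.col_coords.shape[0]
        row_ids = self.row_ids or tuple(f"row{i}" for i in range(nrow))
        col_ids = self.col_ids or tuple(f"col{j}" for j in range(ncol))
        cols = [f"dim{k + 1}" for k in range(d)]
        df = pd.DataFrame(
            np.vstack([self.row_coords, self.col_coords]), columns=cols
        )
        df.insert(0, "point_type", ["participant"] * nrow + ["stimulus"] * ncol)
        df.insert(0, "point_id", list(row_ids) + list(col_ids))
        return df


def counts_to_dissimilarities(matrix: PreferenceMatrix) -> DissimilarityMatrix:
    """Reverse-score preference counts: ``delta = K − count``.

    The most-preferred possible stimulus (count = K) gets dissimilarity 0;
    a never-chosen stimulus gets K. Linear reversal is the minimal metric
    transform; callers wanting another transform can build a
    :class:`DissimilarityMatrix` directly.
    """
    k = matrix.appearances_per_stimulus
    if np.any(matrix.counts > k):
        raise InvalidInputError(f"count exceeds appearances per stimulus K={k}")
    return DissimilarityMatrix(
        delta=k - matrix.counts.astype(float),
        row_ids=matrix.participant_ids,
        col_ids=matrix.stimulus_ids,
    )


def stress(
    row_coords: np.ndarray,
    col_coords: np.ndarray,
    delta: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Normalized stress-1 of a configuration against rectangular ``delta``."""
    row_coords = np.atleast_2d(np.asarray(row_coords, dtype=float))
    col_coords = np.atleast_2d(np.asarray(col_coords, dtype=float))
    delta = np.asarray(delta, dtype=float)
    if delta.shape != (row_coords.shape[0], col_coords.shape[0]):
        raise InvalidInputError("delta shape does not match coordinate shapes")
    w = np.ones_like(delta) if weights is None else np.asarray(weights, dtype=float)
    d = cdist(row_coords, col_coords)
    denom = float(np.sum(w * d**2))
    if denom == 0.0:
        raise DegenerateDataError("all fitted distances are zero; stress undefined")
    return float(np.sqrt(np.sum(w * (delta - d) ** 2) / denom))


def _classical_init(delta: np.ndarray, w: np.ndarray, ndim: int) -> np.ndarray:
    """Classical-scaling start from the completed square dissimilarity matrix.

    Within-set dissimilarities are unobserved; they are imputed by a
    triangle-inequality-consistent average: for two points in the same set,
    the imputed value is the midpoint of the average lower bound
    mean_k |delta_ik − delta_jk| and the average upper bound
    mean_k (delta_ik + delta_jk) over the opposite set.
    """
    n1, n2 = delta.shape

    def impute(block: np.ndarray) -> np.ndarray:
        # block: points x opposite-set dissimilarities
        diff = np.abs(block[:, None, :] - block[None, :, :]).mean(axis=2)
        summ = (block[:, None, :] + block[None, :, :]).mean(axis=2)
        out = 0.5 * (diff + summ)
        np.fill_diagonal(out, 0.0)
        return out

    full = np.zeros((n1 + n2, n1 + n2))
    full[:n1, n1:] = delta
    full[n1:, :n1] = delta.T
    full[:n1, :n1] = impute(delta)
    full[n1:, n1:] = impute(delta.T)

    # Torgerson double-centering
    d2 = full**2
    j = np.eye(n1 + n2) - np.ones((n1 + n2, n1 + n2)) / (n1 + n2)
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1][:ndim]
    coords = evecs[:, order] * np.sqrt(np.clip(evals[order], 0.0, None))
    if coords.shape[1] < ndim:  # degenerate rank; pad
        coords = np.hstack([coords, np.zeros((n1 + n2, ndim - coords.shape[1]))])
    return coords


def _polish_stress1(
    z: np.ndarray,
    d_mat: np.ndarray,
    w: np.ndarray,
    v: np.ndarray,
    n1: int,
    sig: float,
) -> tuple[np.ndarray, float]:
    """Quasi-Newton descent on squared stress-1 from a majorization solution;
    the result is kept only if it strictly lowers the stress."""
    from scipy.optimize import minimize

    n, ndim = z.shape

    def value_and_grad(flat: np.ndarray):
        zc = flat.reshape(n, ndim)
        d = cdist(zc[:n1], zc[n1:])
        eta2 = float(np.sum(w * d**2))
        if eta2 == 0.0:
            return 1e6, np.zeros_like(flat)
        sigma_r = float(np.sum(w * (d_mat - d) ** 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, w * d_mat / d, 0.0)
        b_off = np.zeros((n, n))
        b_off[:n1, n1:] = ratio
        b_off[n1:, :n1] = ratio.T
        b_mat = np.diag(b_off.sum(axis=1)) - b_off
        vz = v @ zc
        grad = (2.0 * vz - 2.0 * (b_mat @ zc)) / eta2 - sigma_r * 2.0 * vz / eta2**2
        return sigma_r / eta2, grad.ravel()

    res = minimize(value_and_grad, z.ravel(), jac=True, method="L-BFGS-B")
    if res.fun >= 0.0 and np.all(np.isfinite(res.x)):
        sig_new = float(np.sqrt(res.fun))
        if sig_new < sig:
            return res.x.reshape(n, ndim), sig_new
    return z, sig


def fit_unfolding(
    delta,
    ndim: int = 2,
    max_iter: int = 5000,
    tol: float = 1e-6,
    init: str = "classical",
    rng_seed: Optional[int] = None,
    weights: Optional[np.ndarray] = None,
    keep_history: bool = False,
    n_init: int = 1,
    polish: bool = True,
) -> UnfoldingSolution:
    """Fit a metric unfolding model to rectangular dissimilarities.

    Parameters
    ----------
    delta
        A :class:`DissimilarityMatrix` or a plain participants × stimuli
        array of nonnegative dissimilarities.
    ndim
        Embedding dimensionality (>= 1); at least ``ndim + 1`` stimuli needed.
    max_iter, tol
        Stop when the per-iteration drop in stress-1 falls below ``tol`` or
        after ``max_iter`` iterations.
    init
        "classical" (default): classical-scaling start from the completed
        square dissimilarity matrix; "random": seeded standard-normal start.
    keep_history
        Record stress-1 after every iteration in ``stress_history``.
    n_init
        Number of starts; with more than one, the first uses ``init`` and the
        rest are seeded random restarts, and the lowest-stress fit is kept.
        Small instances have local minima worth escaping this way.
    polish
        After the majorization loop, refine the configuration by quasi-Newton
        descent on stress-1 itself, accepted only if it lowers the stress.
        Majorization fixed points are stationary for the *raw* stress but not
        for its normalized form, so a short descent on stress-1 proper can
        shave off the remaining gap; the reported history stays monotone.
    """
    if n_init < 1:
        raise InvalidInputError("n_init must be >= 1")
    if n_init > 1:
        seeds = np.random.SeedSequence(rng_seed).generate_state(n_init) % (2**31)
        best = None
        for k in range(n_init):
            sol = fit_unfolding(
                delta,
                ndim=ndim,
                max_iter=max_iter,
                tol=tol,
                init=init if k == 0 else "random",
                rng_seed=int(seeds[k]),
                weights=weights,
                keep_history=keep_history,
                n_init=1,
                polish=polish,
            )
            if best is None or sol.stress < best.stress:
                best = sol
        return best
    if isinstance(delta, DissimilarityMatrix):
        dm = delta
    else:
        dm = DissimilarityMatrix(np.asarray(delta, dtype=float), weights=weights)
    d_mat = dm.delta
    n1, n2 = d_mat.shape
    if ndim < 1:
        raise InvalidInputError("ndim must be >= 1")
    if n2 < ndim + 1:
        raise InvalidInputError(f"need at least ndim+1={ndim + 1} stimuli, got {n2}")
    if np.all(d_mat == 0):
        raise DegenerateDataError("all-zero dissimilarities: configuration undetermined")
    w = np.ones_like(d_mat) if dm.weights is None else dm.weights
    if np.all(w == 0):
        raise InvalidInputError("all weights are zero")

    n = n1 + n2
    w_full = np.zeros((n, n))
    w_full[:n1, n1:] = w
    w_full[n1:, :n1] = w.T
    v = np.diag(w_full.sum(axis=1)) - w_full
    v_pinv = np.linalg.pinv(v)

    if init == "classical":
        z = _classical_init(d_mat, w, ndim)
    elif init == "random":
        rng = np.random.default_rng(rng_seed)
        z = rng.standard_normal((n, ndim))
    else:
        raise InvalidInputError(f"unknown init {init!r}")

    def sigma1_and_dist(zc: np.ndarray):
        d = cdist(zc[:n1], zc[n1:])
        denom = np.sum(w * d**2)
        if denom == 0.0:
            return np.inf, d
        return float(np.sqrt(np.sum(w * (d_mat - d) ** 2) / denom)), d

    # scale the start optimally so the first reported stress is meaningful
    sig, d = sigma1_and_dist(z)
    if np.isfinite(sig):
        t = np.sum(w * d**2)
        z = z * (np.sum(w * d_mat * d) / t)
        sig, d = sigma1_and_dist(z)
    history = [sig] if keep_history else None

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, w * d_mat / d, 0.0)
        b_off = np.zeros((n, n))
        b_off[:n1, n1:] = ratio
        b_off[n1:, :n1] = ratio.T
        b_mat = np.diag(b_off.sum(axis=1)) - b_off
        z_new = v_pinv @ (b_mat @ z)
        if not np.all(np.isfinite(z_new)):
            raise NumericalError(f"non-finite configuration at iteration {it}")
        # optimal rescale keeps stress-1 monotone under majorization
        d_new = cdist(z_new[:n1], z_new[n1:])
        t = np.sum(w * d_new**2)
        if t > 0.0:
            z_new = z_new * (np.sum(w * d_mat * d_new) / t)
        sig_new, d_new = sigma1_and_dist(z_new)
        if keep_history:
            history.append(sig_new)
        if sig_new > sig + 1e-10:
            raise NumericalError(
                f"stress increased at iteration {it}: {sig} -> {sig_new}"
            )
        z, d = z_new, d_new
        if sig - sig_new < tol:
            sig = sig_new
            converged = True
            break
        sig = sig_new

    if polish and sig > 0.0:
        z, sig = _polish_stress1(z, d_mat, w, v, n1, sig)
        if keep_history:
            history.append(sig)

    fitted = cdist(z[:n1], z[n1:])
    delta_var = float(np.var(d_mat))
    ratio_diag = float(np.var(fitted) / delta_var) if delta_var > 0 else np.nan
    return UnfoldingSolution(
        row_coords=z[:n1].copy(),
        col_coords=z[n1:].copy(),
        ndim=ndim,
        stress=sig,
        iterations=it,
        converged=converged,
        rng_seed=rng_seed,
        row_ids=dm.row_ids,
        col_ids=dm.col_ids,
        distance_variance_ratio=ratio_diag,
        stress_history=history,
    )


def select_dimensionality(
    delta,
    dims: Sequence[int] = (1, 2, 3),
    **fit_options,
) -> pd.DataFrame:
    """Fit one unfolding per dimensionality and tabulate (dim, stress,
    iterations, converged), sorted by dim. All fits share the same options
    and seed policy so stress is comparable across rows."""
    if not len(dims):
        raise InvalidInputError("dims must be nonempty")
    rows = []
    for d in sorted(dims):
        sol = fit_unfolding(delta, ndim=d, **fit_options)
        rows.append((d, sol.stress, sol.iterations, sol.converged))
    return pd.DataFrame(rows, columns=["dim", "stress", "iterations", "converged"])


def rotate_to_principal_axes(
    solution: UnfoldingSolution,
    orient_masks: Optional[Sequence[np.ndarray]] = None,
) -> UnfoldingSolution:
    """Rotate the joint configuration so the principal axes of the centered
    stimulus cloud become the coordinate axes (descending variance).

    The same rotation is applied to participants and stimuli, so all
    participant–stimulus distances — hence the stress — are unchanged.
    ``orient_masks`` optionally fixes reflection signs: for axis k with a
    boolean stimulus mask, the sign is chosen so the masked stimuli have the
    larger mean coordinate (e.g. point axis 1 toward the white-face side).
    A rank-deficient stimulus cloud triggers a warning and identity rotation.
    """
    import warnings

    x = solution.col_coords
    if x.shape[0] < 2:
        raise InvalidInputError("need at least 2 stimuli to define principal axes")
    centered = x - x.mean(axis=0)
    cov = centered.T @ centered
    if np.linalg.matrix_rank(cov, tol=1e-12) < solution.ndim:
        warnings.warn("rank-deficient stimulus cloud; applying identity rotation")
        rot = np.eye(solution.ndim)
    else:
        evals, evecs = np.linalg.eigh(cov)
        rot = evecs[:, np.argsort(evals)[::-1]]
    new_rows = solution.row_coords @ rot
    new_cols = solution.col_coords @ rot
    if orient_masks is not None:
        for k, mask in enumerate(orient_masks):
            if mask is None or k >= solution.ndim:
                continue
            mask = np.asarray(mask, dtype=bool)
            if mask.all() or not mask.any():
                continue
            if new_cols[mask, k].mean() < new_cols[~mask, k].mean():
                new_rows[:, k] *= -1
                new_cols[:, k] *= -1
    return UnfoldingSolution(
        row_coords=new_rows,
        col_coords=new_cols,
        ndim=solution.ndim,
        stress=solution.stress,
        iterations=solution.iterations,
        converged=solution.converged,
        rng_seed=solution.rng_seed,
        row_ids=solution.row_ids,
        col_ids=solution.col_ids,
        distance_variance_ratio=solution.distance_variance_ratio,
        stress_history=solution.stress_history,
    )
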