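"""Spatially restricted, temporally concatenated group ICA.

The group decomposition follows the MELODIC convention of *spatial* ICA:
runs are variance-normalized per voxel, row-stacked in time, reduced to d
dimensions by PCA, and unmixed with a fixed-point (FastICA) iteration using
the logcosh contrast and symmetric decorrelation. Several random restarts
are run and the solution with the highest total negentropy is kept.

Conventions frozen here so downstream results are reproducible:

* each component map is z-scored over ROI voxels (mean 0, sd 1);
* sign: the voxel with the largest absolute weight is positive;
* order: descending explained variance of the back-projection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .synthetic import Bold4D

__all__ = ["ICDecomposition", "restrict_to_roi", "concat_group", "group_ica",
           "standardize_maps"]

logger = logging.getLogger(__name__)

_LOGCOSH_GAUSS = 0.3745672075143166  # E[log cosh Z], Z ~ N(0,1)


@dataclass
class ICDecomposition:
    """A d-component spatial decomposition over the ROI voxels."""

    dimension: int
    component_maps: np.ndarray      # d x V_roi, z-scored over ROI voxels
    roi_voxel_index: np.ndarray     # V_roi flat C-order grid indices
    fit_info: dict

    def __post_init__(self) -> None:
        d, v = self.component_maps.shape
        if d != self.dimension:
            raise ValueError("component_maps row count != dimension")
        if v != len(self.roi_voxel_index):
            raise ValueError("component_maps columns != ROI voxel count")


def restrict_to_roi(bold: Bold4D, roi_mask: np.ndarray) -> np.ndarray:
    """T x V_roi matrix of the ROI voxels, in C-order flat-index order.

    ROI voxels absent from the data support contribute all-zero columns (a
    warning is logged); an empty ROI is an error.
    """
    roi_flat = bold.grid.flat_indices(roi_mask)
    if len(roi_flat) == 0:
        raise ValueError("ROI mask is empty")
    # voxel_index is sorted (C-order flatnonzero), so membership is a searchsorted
    pos = np.searchsorted(bold.voxel_index, roi_flat)
    pos_c = np.minimum(pos, len(bold.voxel_index) - 1)
    present = bold.voxel_index[pos_c] == roi_flat
    out = np.zeros((bold.n_timepoints, len(roi_flat)), dtype=np.float64)
    out[:, present] = bold.data[:, pos_c[present]]
    if not present.all():
        logger.warning("%d of %d ROI voxels outside the data support; columns left zero",
                       int((~present).sum()), len(roi_flat))
    return out


def concat_group(matrices: list[np.ndarray], variance_normalize: bool = True
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Row-stack restricted runs; optionally scale each voxel to unit sd per run.

    Returns ``(X, zero_variance)`` where ``zero_variance`` marks voxel columns
    that were constant in at least one run (left at zero and flagged, since
    they carry no signal for the decomposition).
    """
    v0 = matrices[0].shape[1]
    bad = [i for i, m in enumerate(matrices) if m.shape[1] != v0]
    if bad:
        raise ValueError(f"runs {bad} have a different ROI voxel count than run 0 ({v0})")
    zero_var = np.zeros(v0, dtype=bool)
    blocks = []
    for m in matrices:
        m = np.asarray(m, dtype=np.float64)
        if variance_normalize:
            sd = m.std(axis=0, ddof=1)
            const = sd <= 1e-12 * max(1.0, np.abs(m).max())
            zero_var |= const
            scale = np.where(const, 0.0, 1.0 / np.where(const, 1.0, sd))
            m = m * scale
        blocks.append(m)
    X = np.vstack(blocks)
    if zero_var.any():
        X[:, zero_var] = 0.0
        logger.warning("%d zero-variance ROI voxels flagged and zeroed", int(zero_var.sum()))
    return X, zero_var


def _whiten_spatial(X: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten the spatial view of ``X`` (T_total x V) down to d components.

    Returns ``(Y, U, evals)``: Y is V x d with orthogonal unit-second-moment
    columns; U holds the corresponding orthonormal spatial eigenvectors.
    The eigendecomposition is done on the V x V voxel Gram matrix, which is
    cheap for the ROI-sized problems this package targets.

    No spatial centering is applied: voxel series are already demeaned in
    time by preprocessing, and whitening on the raw second moment keeps
    sparse nonnegative maps with disjoint supports orthogonal. Centering
    over voxels would instead make any two such maps strongly negatively
    correlated inside a small ROI and hence unrecoverable by ICA.
    """
    M = X.T  # V x T: voxels as samples, timepoints as features
    K = M @ M.T
    evals, evecs = np.linalg.eigh(K)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = max(M.shape) * np.finfo(float).eps * max(evals[0], 0.0)
    rank = int(np.sum(evals > tol))
    if d > rank:
        raise ValueError(f"requested dimension {d} exceeds data rank {rank}")
    U = evecs[:, :d]
    Y = U * np.sqrt(M.shape[0])  # unit variance over voxels per column
    return Y, U, evals


def standardize_maps(maps: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apply the export conventions to raw spatial maps (d x V): z-score over
    voxels, make the peak-|weight| voxel positive, and order components by
    descending explained variance of the back-projection of ``X``. Invariant
    under row permutation and sign flips of the input, so downstream results
    do not depend on ICA's arbitrary ordering."""
    d, V = maps.shape
    maps = maps - maps.mean(axis=1, keepdims=True)
    maps = maps / maps.std(axis=1, ddof=0, keepdims=True)
    peak = np.argmax(np.abs(maps), axis=1)
    maps = maps * np.sign(maps[np.arange(d), peak])[:, None]
    Xc = X - X.mean(axis=1, keepdims=True)
    A = Xc @ maps.T / V                                     # T_total x d temporal modes
    ev = np.sum(A**2, axis=0) * np.sum(maps**2, axis=1)
    order = np.argsort(-ev)
    return maps[order], ev[order]


def group_ica(X: np.ndarray, d: int, seed: int = 0, n_restarts: int = 5,
              max_iter: int = 500, tol: float = 1e-4,
              roi_voxel_index: np.ndarray | None = None) -> ICDecomposition:
    """Spatial group ICA of the concatenated matrix at dimension ``d``.

    Raises if ``d`` is out of range or exceeds the numerical rank, and if no
    restart converges (the error carries the fit diagnostics).
    """
    T_total, V = X.shape
    if not (1 <= d <= min(T_total, V) - 1):
        raise ValueError(f"dimension must lie in [1, {min(T_total, V) - 1}], got {d}")
    if roi_voxel_index is None:
        roi_voxel_index = np.arange(V)
    Y, U, evals = _whiten_spatial(X, d)

    rng = np.random.default_rng(seed)
    best = None
    restarts = []
    if d == 1:
        # one component: ICA reduces to the principal component itself
        sources, best = Y.copy(), {"converged": True, "n_iter": 0, "negentropy": 0.0}
        restarts.append(best)
    else:
        for k in range(n_restarts):
            rs = int(rng.integers(2**31))
            ica = FastICA(n_components=d, whiten=False, fun="logcosh",
                          algorithm="parallel", max_iter=max_iter, tol=tol,
                          random_state=rs)
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always", ConvergenceWarning)
                S = ica.fit_transform(Y)
            converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
            S = S / S.std(axis=0, ddof=0, keepdims=True)
            neg = float(np.sum((np.mean(np.log(np.cosh(S)), axis=0) - _LOGCOSH_GAUSS) ** 2))
            info = {"seed": rs, "converged": converged,
                    "n_iter": int(getattr(ica, "n_iter_", -1)), "negentropy": neg}
            restarts.append(info)
            if converged and (best is None or neg > best["negentropy"]):
                best, sources = info, S
        if best is None:
            raise RuntimeError(f"group ICA did not converge in {n_restarts} restarts; "
                               f"fit_info={restarts}")

    maps, ev = standardize_maps(sources.T.astype(np.float64), X)

    fit_info = {"seed": int(seed), "dimension": int(d),
                "converged": bool(best["converged"]), "n_iter": best["n_iter"],
                "negentropy": best["negentropy"], "n_restarts": len(restarts),
                "explained_variance": ev.tolist()}
    return ICDecomposition(dimension=d, component_maps=maps,
                           roi_voxel_index=np.asarray(roi_voxel_index), fit_info=fit_info)
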