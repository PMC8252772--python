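"""Nuisance-signal regression and demeaning.

The only preprocessing performed here is the removal of CSF-like and WM-like
mean signals by per-run least-squares residualization, followed by voxelwise
demeaning. Regression is applied per run; runs are concatenated only
afterwards, which avoids inter-run mean artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .synthetic import Anatomy, Bold4D

__all__ = ["ConfoundSet", "extract_confounds", "regress_confounds", "preprocess_run"]


@dataclass
class ConfoundSet:
    """T x c nuisance regressors for one run (demeaned), plus an intercept.

    ``design()`` returns the full design matrix with the intercept column
    first; the stored ``regressors`` hold only the nuisance columns.
    """

    regressors: np.ndarray  # T x c, demeaned
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        # all-zero columns (e.g. from a constant image) carry no information
        # and are tolerated; collinearity among the real columns is an error
        live = np.abs(self.regressors).max(axis=0) > 0
        X = np.column_stack([np.ones(self.regressors.shape[0]),
                             self.regressors[:, live]])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("confound matrix is rank deficient (after intercept)")

    @property
    def n_timepoints(self) -> int:
        return int(self.regressors.shape[0])

    def design(self) -> np.ndarray:
        T = self.regressors.shape[0]
        return np.column_stack([np.ones(T), self.regressors])


def extract_confounds(bold: Bold4D, nuisance_masks: dict[str, np.ndarray]) -> ConfoundSet:
    """Mean signal over each nuisance mask, demeaned, one column per mask."""
    cols, names = [], []
    for name in sorted(nuisance_masks):
        mask = nuisance_masks[name]
        flat = bold.grid.flat_indices(mask)
        sel = np.isin(bold.voxel_index, flat)
        if not sel.any():
            raise ValueError(f"nuisance mask '{name}' is empty on the data grid")
        series = bold.data[:, sel].mean(axis=1, dtype=np.float64)
        cols.append(series - series.mean())
        names.append(name)
    return ConfoundSet(regressors=np.column_stack(cols), names=tuple(names))


def regress_confounds(bold: Bold4D, conf: ConfoundSet | None = None) -> Bold4D:
    """Residualize every voxel series against the confounds and demean.

    With ``conf=None`` (or zero nuisance columns) this reduces to plain
    demeaning. The result is the orthogonal projection of the data onto the
    complement of the confound span, so applying it twice is a no-op.
    """
    T = bold.n_timepoints
    if conf is None:
        X = np.ones((T, 1))
    else:
        if conf.n_timepoints != T:
            raise ValueError("confound length does not match the run")
        X = conf.design()
    if T <= X.shape[1]:
        raise ValueError(f"need T > {X.shape[1]} timepoints for {X.shape[1] - 1} confounds")
    Y = bold.data.astype(np.float64, copy=False)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta  # float64: keeps residuals orthogonal to machine precision
    return replace(bold, data=resid)


def preprocess_run(bold: Bold4D, anatomy: Anatomy) -> Bold4D:
    """Convenience: extract CSF/WM confounds from ``anatomy`` and residualize."""
    return regress_confounds(bold, extract_confounds(bold, anatomy.nuisance_masks))
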