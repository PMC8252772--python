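"""Dual regression: group components -> participant time courses -> FC maps.

Stage 1 regresses all group component maps jointly (with an intercept over
voxels) against each volume of the participant's ROI-restricted data, giving
one time course per component. Stage 2 regresses those time courses jointly
(variance-normalized, with an intercept) against every brain voxel's series.

Each stage-2 regression coefficient is converted to a *partial correlation*
before the Fisher transform: the raw coefficient is unbounded, so atanh of
it is ill-defined, whereas the partial correlation lives in (-1, 1). A
``coefficient_scale="raw"`` mode is kept for comparison. Partial
correlations are clamped to |r| <= 1 - 1e-7 before atanh.

Group-level one-sample maps come either from a parametric one-sample t test
(t mapped to a normal quantile) or from voxelwise sign-flipping permutation
p-values; the sign-flip path also reports randomise-style max-statistic
family-wise p-values in its diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.special import ndtri

from .ica import ICDecomposition

__all__ = ["FCMapSet", "GroupMap", "stage1_timecourses", "stage2_maps",
           "group_onesample_map", "R_CLAMP"]

R_CLAMP = 1.0 - 1e-7   # |partial r| clamp before atanh
_Z_CLIP = 37.0         # atanh(R_CLAMP) ~ 8.4; normal quantiles clipped well beyond


@dataclass
class GroupMap:
    """Group one-sample z map for one component, with degeneracy flags."""

    z: np.ndarray
    flagged: np.ndarray            # zero-variance voxels, z forced to 0
    method: str
    extras: dict = field(default_factory=dict)


@dataclass
class FCMapSet:
    """Participant- and group-level whole-brain FC maps for one decomposition."""

    dimension: int
    participant_ids: list[str]
    participant_maps: np.ndarray   # N x d x V_brain Fisher-z
    group_maps: list[GroupMap]     # one per component
    stage1_timecourses: dict[str, np.ndarray]  # pid -> T_p x d

    @property
    def group_z(self) -> np.ndarray:
        return np.stack([g.z for g in self.group_maps])


def stage1_timecourses(roi_data: np.ndarray, ic: ICDecomposition) -> np.ndarray:
    """T x d time courses from the joint spatial regression of the component
    maps (plus intercept) on each volume of the ROI-restricted data."""
    T, V = roi_data.shape
    if V != ic.component_maps.shape[1]:
        raise ValueError("ROI data and component maps disagree on voxel count")
    D = np.column_stack([np.ones(V), ic.component_maps.T])   # V x (d+1)
    cond = np.linalg.cond(D)
    if cond > 1e8:
        raise ValueError(f"component maps are collinear (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(D, roi_data.T, rcond=None)    # (d+1) x T
    return beta[1:].T.copy()


def stage2_maps(data: np.ndarray, courses: np.ndarray,
                coefficient_scale: str = "partial_r") -> tuple[np.ndarray, np.ndarray]:
    """d whole-brain Fisher-z maps from the joint temporal regression of the
    stage-1 courses on every voxel series.

    Returns ``(zmaps, flagged)`` with zmaps d x V; ``flagged`` marks constant
    voxels whose z is set to 0 by contract.
    """
    T, V = data.shape
    d = courses.shape[1]
    if courses.shape[0] != T:
        raise ValueError("courses and data disagree on T")
    if T <= d + 1:
        raise ValueError(f"need T > d + 1 (= {d + 1}), got T = {T}")
    sd = courses.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("a stage-1 course is constant; cannot variance-normalize")
    G = np.column_stack([np.ones(T), (courses - courses.mean(axis=0)) / sd])
    GtG = G.T @ G
    GtY = G.T @ data
    beta = np.linalg.solve(GtG, GtY)                         # (d+1) x V
    dof = T - d - 1
    rss = np.einsum("tv,tv->v", data, data) - np.einsum("kv,kv->v", beta, GtY)
    rss = np.maximum(rss, 0.0)
    col_var = data.var(axis=0, ddof=0) * T
    flagged = col_var <= 1e-12 * max(1.0, float(col_var.max(initial=0.0)))
    sigma2 = rss / dof
    inv_diag = np.diag(np.linalg.inv(GtG))[1:]               # per-regressor leverage
    if coefficient_scale == "raw":
        z = np.arctanh(np.clip(beta[1:], -R_CLAMP, R_CLAMP))
    elif coefficient_scale == "partial_r":
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[1:] / np.sqrt(sigma2[None, :] * inv_diag[:, None])
            t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no noise
            r = np.where(np.isinf(t), np.sign(t), t / np.sqrt(t**2 + dof))
        z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    else:
        raise ValueError(f"unknown coefficient_scale {coefficient_scale!r}")
    z[:, flagged] = 0.0
    return z, flagged


def group_onesample_map(participant_maps: np.ndarray, method: str = "parametric",
                        n_perm: int = 1000, seed: int = 0) -> GroupMap:
    """One-sample group map over participants for a single component.

    ``participant_maps`` is N x V of Fisher-z values. ``parametric`` converts
    the one-sample t statistic to a z score through the t CDF; ``signflip``
    uses voxelwise one-sided sign-flipping permutation p-values (plus
    max-statistic FWE p-values in ``extras``). Zero-variance voxels are
    flagged and set to z = 0.
    """
    Y = np.asarray(participant_maps, dtype=np.float64)
    N, V = Y.shape
    if N < 3:
        raise ValueError(f"need >= 3 participants, got {N}")
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    flagged = sd <= 1e-12 * max(1.0, float(np.abs(Y).max(initial=0.0)))
    safe_sd = np.where(flagged, 1.0, sd)
    t_obs = mean / (safe_sd / np.sqrt(N))
    if method == "parametric":
        # z via the normal quantile of the t CDF, symmetric and overflow-safe
        z = -ndtri(stats.t.sf(t_obs, df=N - 1))
        z = np.clip(np.nan_to_num(z), -_Z_CLIP, _Z_CLIP)
        extras = {}
    elif method == "signflip":
        rng = np.random.default_rng(seed)
        flips = rng.choice([-1.0, 1.0], size=(n_perm, N))
        flips[0] = 1.0  # include the identity permutation
        m = flips @ Y / N
        s2 = (Y**2).sum(axis=0) / N  # E[y^2] is flip-invariant
        se = np.sqrt(np.maximum(s2 - m**2, 0.0) * N / (N - 1)) / np.sqrt(N)
        se = np.where(se <= 0, 1.0, se)
        t_perm = m / se
        exceed = (t_perm >= t_obs[None, :]).sum(axis=0)
        p = exceed / n_perm  # identity flip guarantees p >= 1/n_perm
        z = np.clip(-ndtri(p), -_Z_CLIP, _Z_CLIP)
        t_max = t_perm.max(axis=1)
        p_fwe = (t_max[:, None] >= t_obs[None, :]).sum(axis=0) / n_perm
        extras = {"p_voxel": p, "p_fwe": p_fwe, "n_perm": n_perm}
    else:
        raise ValueError(f"unknown method {method!r}")
    z = np.where(flagged, 0.0, z)
    return GroupMap(z=z, flagged=flagged, method=method, extras=extras)
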