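"""Region-level mixed-effects model and effect contrasts.

Participant FC maps are intersected with each participant's own atlas and the
mean Fisher-z per (region, hemisphere, FC map) is modeled as

    mean_z ~ hemisphere + fc_map * region + (1 | participant)

with a random intercept per participant. Type III Wald tests are reported
for every fixed term. Post-hoc "effect" contrasts compare each region's
marginal mean (averaged over hemisphere) with the mean of all other regions
within the same FC map, exactly the ranking statistic used downstream:
z_ratio = estimate / se, Bonferroni-adjusted p over regions x FC maps.

Degrees of freedom: test statistics use the large-sample normal / chi-square
approximation (recorded as ``df_method="normal"`` in the fit); the post-hoc
statistic of interest is the z-ratio itself, which does not depend on a
small-sample df correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .synthetic import HEMI_CODE_OFFSET, VolumeGrid

__all__ = ["LMMFit", "extract_region_means", "validate_region_sample",
           "fit_lmm", "effect_contrasts", "marginal_mean_rows"]

_FORMULA = "mean_z ~ C(hemisphere, Sum) + C(fc_map, Sum) * C(region, Sum)"


def extract_region_means(participant_maps: Mapping[str, np.ndarray],
                         labels_by_pid: Mapping[str, np.ndarray],
                         grid: VolumeGrid, voxel_index: np.ndarray,
                         hemisphere_from: str = "code") -> pd.DataFrame:
    """Long table of mean map values per (participant, hemisphere, region, fc_map).

    ``participant_maps[pid]`` is an n_fc x V_brain array on the shared voxel
    linearization; ``labels_by_pid[pid]`` is that participant's own label
    volume. ``hemisphere_from="code"`` decodes right-hemisphere labels as
    code + HEMI_CODE_OFFSET (atlas convention); ``"midline"`` assigns
    hemisphere from the voxel x position (subfield convention, where the same
    label codes appear bilaterally). Empty intersections are omitted with a
    warning.
    """
    if hemisphere_from not in ("code", "midline"):
        raise ValueError("hemisphere_from must be 'code' or 'midline'")
    left_flat = grid.left_hemisphere_mask().ravel()[voxel_index]
    binned: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    all_regions: set[int] = set()
    for pid in sorted(participant_maps):
        maps = np.asarray(participant_maps[pid], dtype=np.float64)
        labels = labels_by_pid[pid]
        if labels.shape != grid.shape:
            raise ValueError(f"labels for {pid} are not on the map grid {grid.shape}")
        lab_flat = labels.ravel()[voxel_index].astype(np.int64)
        if hemisphere_from == "code":
            hemi_is_left = lab_flat < HEMI_CODE_OFFSET
            region = np.where(lab_flat > HEMI_CODE_OFFSET,
                              lab_flat - HEMI_CODE_OFFSET, lab_flat)
        else:
            hemi_is_left = left_flat
            region = lab_flat
        present = region > 0
        key = (region * 2 + (~hemi_is_left).astype(np.int64))[present]  # (region, hemi)
        counts = np.bincount(key)
        sums = np.stack([np.bincount(key, weights=m[present], minlength=len(counts))
                         for m in maps])
        binned[pid] = (counts, sums, maps)
        all_regions |= set((np.flatnonzero(counts) // 2).tolist())
    rows, missing = [], set()
    for pid, (counts, sums, maps) in binned.items():
        for f in range(maps.shape[0]):
            for r in sorted(all_regions):
                for h, code in (("L", 0), ("R", 1)):
                    k = 2 * r + code
                    if k < len(counts) and counts[k] > 0:
                        rows.append((pid, h, r, f, sums[f, k] / counts[k]))
                    else:
                        missing.add((pid, h, r))
    if missing:
        warnings.warn(f"{len(missing)} empty (participant, hemisphere, region) "
                      f"intersections omitted", stacklevel=2)
    df = pd.DataFrame(rows, columns=["participant_id", "hemisphere", "region",
                                     "fc_map", "mean_z"])
    return df.sort_values(["participant_id", "fc_map", "region", "hemisphere"],
                          ignore_index=True)


def validate_region_sample(df: pd.DataFrame) -> None:
    required = {"participant_id", "hemisphere", "region", "fc_map", "mean_z"}
    if not required <= set(df.columns):
        raise ValueError(f"region sample missing columns {required - set(df.columns)}")
    if not np.all(np.isfinite(df["mean_z"])):
        raise ValueError("mean_z contains non-finite values")
    dup = df.duplicated(["participant_id", "hemisphere", "region", "fc_map"])
    if dup.any():
        raise ValueError("duplicate (participant, hemisphere, region, fc_map) rows")
    expected = (df["participant_id"].nunique() * df["hemisphere"].nunique()
                * df["region"].nunique() * df["fc_map"].nunique())
    if len(df) < expected:
        warnings.warn(f"unbalanced design: {expected - len(df)} missing cells",
                      stacklevel=2)


@dataclass
class LMMFit:
    """Fitted mixed (or fallback OLS) model plus everything contrasts need."""

    params: np.ndarray             # fixed-effect estimates
    cov: np.ndarray                # covariance of the fixed effects
    design_info: object            # patsy design info for new design rows
    data: pd.DataFrame
    anova: pd.DataFrame            # Type III Wald tests per fixed term
    regions: list
    fc_maps: list
    hemispheres: list
    random_intercept: bool
    singular: bool
    df_method: str
    participant_var: float
    resid_var: float

    @property
    def interaction_p(self) -> float:
        """p of the fc_map x region interaction; nan when the design has a
        single FC map (the term is then empty and the gate does not apply)."""
        row = self.anova.loc[self.anova["term"].str.contains(":")]
        if len(row) == 0:
            return float("nan")
        return float(row["p"].iloc[0])


def _type3_anova(params: np.ndarray, cov: np.ndarray, design_info) -> pd.DataFrame:
    """Wald chi-square per model term (sum-coded design => Type III tests)."""
    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(sl.start, sl.stop)
        if len(idx) == 0:  # factor with a single level contributes no columns
            continue
        b = params[idx]
        Vb = cov[np.ix_(idx, idx)]
        if np.abs(b).max() < 1e-10 * max(1.0, np.abs(params).max()):
            stat = 0.0  # degenerate constant response: 0/0 Wald ratio is 0
        else:
            try:
                stat = float(b @ np.linalg.solve(Vb, b))
            except np.linalg.LinAlgError:
                stat = float(b @ np.linalg.pinv(Vb) @ b)
        k = len(idx)
        rows.append((term, k, stat, stat / k, float(stats.chi2.sf(stat, k))))
    return pd.DataFrame(rows, columns=["term", "df", "chi2", "F_approx", "p"])


def fit_lmm(data: pd.DataFrame, include_random: bool = True) -> LMMFit:
    """Fit the hemisphere + fc_map x region model with a participant random
    intercept. A singular fit (participant variance collapsing to zero or a
    failed optimization) falls back to OLS with a warning and is flagged.
    ``include_random=False`` forces the OLS path (used by exactness checks).
    """
    validate_region_sample(data)
    for col, lo in (("hemisphere", 2), ("region", 2), ("fc_map", 1)):
        if data[col].nunique() < lo:
            raise ValueError(f"need >= {lo} levels of {col}")
    if include_random and data["participant_id"].nunique() < 3:
        raise ValueError("need >= 3 participants for the mixed model")
    df = data.copy()

    singular = False
    participant_var = 0.0
    if include_random:
        model = smf.mixedlm(_FORMULA, df, groups=df["participant_id"])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)  # singular-cov notices
                res = model.fit(reml=True, method="lbfgs")
            participant_var = float(np.asarray(res.cov_re).ravel()[0])
            resid_var = float(res.scale)
            if not np.isfinite(participant_var) or participant_var <= 1e-10 * resid_var:
                singular = True
        except (np.linalg.LinAlgError, ValueError):
            singular = True
        if singular:
            warnings.warn("singular mixed fit (participant variance ~ 0); "
                          "refitting as fixed-effects OLS", stacklevel=2)
    if include_random and not singular:
        k_fe = len(res.fe_params)
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        design_info = res.model.data.design_info
    else:
        ols = smf.ols(_FORMULA, df).fit()
        params = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        design_info = ols.model.data.design_info
        resid_var = float(ols.mse_resid)
    anova = _type3_anova(params, cov, design_info)
    return LMMFit(params=params, cov=cov, design_info=design_info, data=df,
                  anova=anova,
                  regions=sorted(df["region"].unique().tolist()),
                  fc_maps=sorted(df["fc_map"].unique().tolist()),
                  hemispheres=sorted(df["hemisphere"].unique().tolist()),
                  random_intercept=include_random and not singular,
                  singular=singular, df_method="normal",
                  participant_var=participant_var, resid_var=resid_var)


def marginal_mean_rows(fit: LMMFit) -> dict[tuple, np.ndarray]:
    """Design-matrix row of the marginal mean for each (fc_map, region) cell,
    averaged over hemisphere levels. est = row @ params, the estimated
    marginal mean on the model scale."""
    from patsy import build_design_matrices

    rows = {}
    for f in fit.fc_maps:
        for r in fit.regions:
            cells = pd.DataFrame({"hemisphere": fit.hemispheres,
                                  "fc_map": [f] * len(fit.hemispheres),
                                  "region": [r] * len(fit.hemispheres),
                                  "mean_z": 0.0})
            (X,) = build_design_matrices([fit.design_info], cells)
            rows[(f, r)] = np.asarray(X).mean(axis=0)
    return rows


def effect_contrasts(fit: LMMFit, family_size: int | None = None,
                     variant: str = "mean_of_others") -> pd.DataFrame:
    """Per (fc_map, region): region marginal mean vs the other regions.

    ``variant="mean_of_others"`` contrasts against the unweighted mean of the
    remaining regions; ``"grand_mean"`` against the mean of all regions
    (the two differ by the factor R/(R-1) only). Bonferroni family defaults
    to regions x fc_maps.
    """
    R = len(fit.regions)
    if R < 2:
        raise ValueError("need >= 2 regions for effect contrasts")
    if variant not in ("mean_of_others", "grand_mean"):
        raise ValueError(f"unknown variant {variant!r}")
    mm = marginal_mean_rows(fit)
    if family_size is None:
        family_size = R * len(fit.fc_maps)
    out = []
    for f in fit.fc_maps:
        rows = {r: mm[(f, r)] for r in fit.regions}
        mean_all = np.mean(list(rows.values()), axis=0)
        for r in fit.regions:
            if variant == "mean_of_others":
                L = rows[r] - (mean_all * R - rows[r]) / (R - 1)
            else:
                L = rows[r] - mean_all
            est = float(L @ fit.params)
            se = float(np.sqrt(L @ fit.cov @ L))
            z = est / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            out.append((f, r, est, se, z, p, min(1.0, p * family_size)))
    df = pd.DataFrame(out, columns=["fc_map", "region", "estimate", "se",
                                    "z_ratio", "p_raw", "p_adj"])
    for f in fit.fc_maps:  # effect contrasts are zero-sum within each fc_map
        s = df.loc[df["fc_map"] == f, "estimate"].sum()
        if abs(s) > 1e-8 * max(1.0, df["estimate"].abs().max()):
            raise AssertionError(f"effect contrasts for fc_map {f} sum to {s}, not 0")
    return df
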