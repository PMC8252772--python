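"""Hippocampal subfield contribution ranking.

The same mixed model used for whole-brain regions is refitted with the six
subfield labels (CA1, CA3, CA4, DG, SUB, ML) as the region factor. All
S(S-1)/2 pairwise marginal-mean differences are computed within each FC map,
each summarized by its z-ratio (estimate / se). Per subfield the signed
pairwise z-ratios are summed; subfields with a positive sum are ranked in
descending order. Raw z-ratios serve as a ranking statistic here, so no
multiplicity correction is applied inside the ranking.

ML participates in the model and the sums (its central position sharpens the
partial estimates of its neighbors) but is anatomically interpretive rather
than a driver of connectivity.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .region_stats import LMMFit, extract_region_means, marginal_mean_rows
from .synthetic import SUBFIELD_NAMES, VolumeGrid

__all__ = ["extract_subfield_means", "pairwise_contrasts", "rank_subfields",
           "SUBFIELD_NAMES"]


def extract_subfield_means(participant_maps: Mapping[str, np.ndarray],
                           subfields_by_pid: Mapping[str, np.ndarray],
                           grid: VolumeGrid, voxel_index: np.ndarray) -> pd.DataFrame:
    """Mean FC-map value per (participant, hemisphere, subfield, fc_map).

    Subfield labels carry no hemisphere coding, so hemisphere is assigned
    from the voxel position relative to the midline.
    """
    df = extract_region_means(participant_maps, subfields_by_pid, grid,
                              voxel_index, hemisphere_from="midline")
    df["region"] = df["region"].map(SUBFIELD_NAMES)
    return df


def pairwise_contrasts(fit: LMMFit) -> pd.DataFrame:
    """All unordered pairwise marginal-mean differences within each FC map.

    Rows are (fc_map, subfield_a, subfield_b, estimate, se, z_ratio, p_raw)
    with estimate = mean(a) - mean(b); S subfields give S(S-1)/2 rows per
    FC map, antisymmetric under swapping a and b.
    """
    if len(fit.regions) < 2:
        raise ValueError("need >= 2 subfields for pairwise contrasts")
    mm = marginal_mean_rows(fit)
    out = []
    for f in fit.fc_maps:
        for a, b in combinations(fit.regions, 2):
            L = mm[(f, a)] - mm[(f, b)]
            est = float(L @ fit.params)
            se = float(np.sqrt(L @ fit.cov @ L))
            z = est / se if se > 0 else 0.0
            out.append((f, a, b, est, se, z, 2.0 * stats.norm.sf(abs(z))))
    return pd.DataFrame(out, columns=["fc_map", "subfield_a", "subfield_b",
                                      "estimate", "se", "z_ratio", "p_raw"])


def rank_subfields(pairs: pd.DataFrame) -> pd.DataFrame:
    """Summed signed z-ratios per subfield and FC map, thresholded at > 0.

    Each pair contributes +z to its first member and -z to its second, so the
    pre-threshold sums are zero-sum within an FC map (asserted). The returned
    table keeps all subfields (column ``summed_z_ratio``); only those with a
    positive sum receive a rank (1 = largest), others get rank <NA>.
    """
    out = []
    for f, grp in pairs.groupby("fc_map"):
        subs = sorted(set(grp["subfield_a"]) | set(grp["subfield_b"]),
                      key=lambda s: str(s))
        n = len(subs)
        if len(grp) != n * (n - 1) // 2:
            raise ValueError(f"fc_map {f}: expected {n * (n - 1) // 2} pairs, "
                             f"got {len(grp)}")
        sums = {s: 0.0 for s in subs}
        for _, row in grp.iterrows():
            sums[row["subfield_a"]] += row["z_ratio"]
            sums[row["subfield_b"]] -= row["z_ratio"]
        total = sum(sums.values())
        if abs(total) > 1e-8 * max(1.0, max(abs(v) for v in sums.values())):
            raise AssertionError(f"pre-threshold summed z-ratios sum to {total}, not 0")
        ranked = sorted((s for s in subs if sums[s] > 0), key=lambda s: -sums[s])
        rank_of = {s: i + 1 for i, s in enumerate(ranked)}
        for s in subs:
            out.append((f, s, sums[s], rank_of.get(s)))
    df = pd.DataFrame(out, columns=["fc_map", "subfield", "summed_z_ratio", "rank"])
    df["rank"] = df["rank"].astype("Int64")
    return df.sort_values(["fc_map", "summed_z_ratio"],
                          ascending=[True, False], ignore_index=True)
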