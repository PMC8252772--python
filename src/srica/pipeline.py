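"""End-to-end pipeline: preprocess -> srICA sweep -> dual regression ->
network matching -> region statistics -> subfield ranking.

``analyze_cohort`` runs everything in memory and returns a result object;
``run_pipeline`` wraps it with artifact writing (TSV tables, NIfTI maps,
provenance JSON) and ``write_report`` renders the human-readable summary
tables (correlation matrix, per-IC region contrasts, subfield ranking,
matched-component counts per dimension).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .synthetic import (Anatomy, Bold4D, Cohort, CohortConfig, generate_cohort,
                        load_cohort)
from .preprocess import preprocess_run
from .ica import ICDecomposition, concat_group, group_ica, restrict_to_roi
from .dualreg import FCMapSet, group_onesample_map, stage1_timecourses, stage2_maps
from .matching import (CorrelationMatrix, OptimalDimension, SelectionParams,
                       SelectionResult, optimize_dimension,
                       spatial_correlation_matrix, select_components)
from .region_stats import effect_contrasts, extract_region_means, fit_lmm
from .subfields import extract_subfield_means, pairwise_contrasts, rank_subfields

__all__ = ["PipelineConfig", "PipelineResult", "PipelineError",
           "analyze_cohort", "run_pipeline", "write_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable round-trip via to/from_json."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_manifest: str | None = None   # load this cohort instead of simulating
    selection: SelectionParams = field(default_factory=SelectionParams)
    ica_seed: int = 0
    ica_restarts: int = 5
    group_map_method: str = "parametric"   # or "signflip"
    n_perm: int = 1000
    coefficient_scale: str = "partial_r"
    variance_normalize: bool = True
    interaction_alpha: float = 0.05
    bonferroni_family: int | None = None
    contrast_variant: str = "mean_of_others"
    display_z: float = 4.0               # report-only threshold, never computational
    out_dir: str | None = None

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        cc = d.pop("cohort")
        cc["grid_shape"] = tuple(cc["grid_shape"])
        sel = d.pop("selection")
        sel["d_range"] = tuple(sel["d_range"])
        return cls(cohort=CohortConfig(**cc), selection=SelectionParams(**sel), **d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: Cohort
    optimal: OptimalDimension
    corr_by_dim: dict[int, CorrelationMatrix]
    ic: ICDecomposition | None
    fcmaps: FCMapSet | None
    selection: SelectionResult | None
    region_sample: pd.DataFrame | None = None
    region_anova: pd.DataFrame | None = None
    region_contrasts: pd.DataFrame | None = None
    subfield_sample: pd.DataFrame | None = None
    subfield_anova: pd.DataFrame | None = None
    subfield_pairwise: pd.DataFrame | None = None
    subfield_ranking: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


def _prepare(cohort: Cohort, config: PipelineConfig):
    """Preprocess all runs and build the restriction/concatenation products
    shared by every dimension of the sweep."""
    template = cohort.template
    clean: dict[str, list[Bold4D]] = {}
    for pid in cohort.participant_ids:
        clean[pid] = [preprocess_run(b, template) for b in cohort.runs_for(pid)]
    roi_by_run = []
    for pid in cohort.participant_ids:
        for b in clean[pid]:
            roi_by_run.append(restrict_to_roi(b, template.roi_mask))
    X, zero_var = concat_group(roi_by_run, variance_normalize=config.variance_normalize)
    # per-participant concatenations for dual regression (runs stacked in order)
    roi_concat = {}
    full_concat = {}
    for pid in cohort.participant_ids:
        runs = clean[pid]
        roi_concat[pid] = np.vstack([restrict_to_roi(b, template.roi_mask) for b in runs])
        full_concat[pid] = np.vstack([b.data for b in runs])
    roi_index = template.grid.flat_indices(template.roi_mask)
    return X, roi_index, roi_concat, full_concat


def _dual_regress_all(cohort: Cohort, config: PipelineConfig, ic: ICDecomposition,
                      roi_concat, full_concat) -> FCMapSet:
    pids = cohort.participant_ids
    pmaps, courses_by_pid = [], {}
    for pid in pids:
        courses = stage1_timecourses(roi_concat[pid], ic)
        zmaps, _ = stage2_maps(full_concat[pid], courses,
                               coefficient_scale=config.coefficient_scale)
        courses_by_pid[pid] = courses
        pmaps.append(zmaps)
    pmaps = np.stack(pmaps)                     # N x d x V
    group_maps = [group_onesample_map(pmaps[:, k, :], method=config.group_map_method,
                                      n_perm=config.n_perm,
                                      seed=config.ica_seed + 7919 * (k + 1))
                  for k in range(ic.dimension)]
    return FCMapSet(dimension=ic.dimension, participant_ids=list(pids),
                    participant_maps=pmaps, group_maps=group_maps,
                    stage1_timecourses=courses_by_pid)


def analyze_cohort(cohort: Cohort, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on an in-memory cohort."""
    if config is None:
        config = PipelineConfig()
    template = cohort.template
    try:
        X, roi_index, roi_concat, full_concat = _prepare(cohort, config)
    except Exception as exc:
        raise PipelineError("preprocess", str(exc)) from exc

    brain_flat = template.grid.flat_indices(template.brain_mask)
    templates = np.stack([net.ravel()[brain_flat] for net in template.networks])
    corr_by_dim: dict[int, CorrelationMatrix] = {}

    def run_dimension(d: int) -> CorrelationMatrix:
        ic = group_ica(X, d, seed=config.ica_seed, n_restarts=config.ica_restarts,
                       roi_voxel_index=roi_index)
        fc = _dual_regress_all(cohort, config, ic, roi_concat, full_concat)
        C = spatial_correlation_matrix(fc.group_z, templates, dimension=d)
        corr_by_dim[d] = C
        return C

    optimal = optimize_dimension(run_dimension, config.selection)
    d_star = optimal.d_star
    notes = [f"optimal dimension {d_star} "
             f"(counts {optimal.counts_by_dimension})"]

    ic = fc = selection = None
    result = PipelineResult(config=config, cohort=cohort, optimal=optimal,
                            corr_by_dim=corr_by_dim, ic=None, fcmaps=None,
                            selection=None, notes=notes)
    if d_star in optimal.failures:
        return result
    try:
        ic = group_ica(X, d_star, seed=config.ica_seed, n_restarts=config.ica_restarts,
                       roi_voxel_index=roi_index)
        fc = _dual_regress_all(cohort, config, ic, roi_concat, full_concat)
        selection = optimal.selections.get(d_star) or select_components(
            spatial_correlation_matrix(fc.group_z, templates, dimension=d_star),
            config.selection)
    except Exception as exc:
        raise PipelineError("dual_regression", str(exc)) from exc
    result.ic, result.fcmaps, result.selection = ic, fc, selection
    if selection.count == 0:
        result.notes.append("no components matched any reference network; "
                            "group statistics skipped")
        return result

    comp_idx = [i for i, _, _ in selection.selected]
    sel_maps = {pid: fc.participant_maps[n, comp_idx, :]
                for n, pid in enumerate(fc.participant_ids)}
    grid = template.grid
    try:
        rs = extract_region_means(sel_maps,
                                  {pid: an.atlas for pid, an in
                                   cohort.participant_anatomy.items()},
                                  grid, brain_flat, hemisphere_from="code")
        rfit = fit_lmm(rs)
        result.region_sample, result.region_anova = rs, rfit.anova
        if len(comp_idx) < 2 or rfit.interaction_p < config.interaction_alpha:
            result.region_contrasts = effect_contrasts(
                rfit, family_size=config.bonferroni_family,
                variant=config.contrast_variant)
        else:
            result.notes.append(
                f"region fc_map x region interaction p = {rfit.interaction_p:.3g} "
                f">= {config.interaction_alpha}; post-hoc contrasts skipped")
    except Exception as exc:
        raise PipelineError("region_stats", str(exc)) from exc

    try:
        ss = extract_subfield_means(sel_maps,
                                    {pid: an.subfields for pid, an in
                                     cohort.participant_anatomy.items()},
                                    grid, brain_flat)
        sfit = fit_lmm(ss)
        result.subfield_sample, result.subfield_anova = ss, sfit.anova
        # the interaction gate applies only when there are >= 2 FC maps
        if len(comp_idx) < 2 or sfit.interaction_p < config.interaction_alpha:
            pairs = pairwise_contrasts(sfit)
            result.subfield_pairwise = pairs
            result.subfield_ranking = rank_subfields(pairs)
        else:
            result.notes.append(
                f"subfield fc_map x region interaction p = {sfit.interaction_p:.3g} "
                f">= {config.interaction_alpha}; ranking skipped")
    except Exception as exc:
        raise PipelineError("subfield_ranking", str(exc)) from exc
    return result


# ---------------------------------------------------------------------------
# artifact writing
# ---------------------------------------------------------------------------


def _write_nifti(path: Path, maps: np.ndarray, voxel_index: np.ndarray,
                 grid) -> None:
    import nibabel as nib

    vols = np.zeros((grid.n_voxels, maps.shape[0]), dtype=np.float32)
    vols[voxel_index] = maps.T
    nib.save(nib.Nifti1Image(vols.reshape(*grid.shape, maps.shape[0]),
                             grid.affine()), path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the pipeline and persist every intermediate artifact.

    Returns the run directory. Raises :class:`PipelineError` naming the
    failing stage; artifacts produced before the failure stay on disk.
    """
    if config.out_dir is None:
        raise ValueError("config.out_dir must be set for run_pipeline")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json() + "\n")

    if config.cohort_manifest is not None:
        mp = Path(config.cohort_manifest)
        if not mp.exists():
            raise PipelineError("load_cohort", f"missing cohort manifest: {mp}")
        cohort = load_cohort(mp)
    else:
        cohort = generate_cohort(config.cohort)

    res = analyze_cohort(cohort, config)
    grid = cohort.template.grid
    brain_flat = grid.flat_indices(cohort.template.brain_mask)

    counts = pd.DataFrame(sorted(res.optimal.counts_by_dimension.items()),
                          columns=["dimension", "n_selected"])
    counts.to_csv(out / "counts_by_dimension.tsv", sep="\t", index=False)
    for d, C in res.corr_by_dim.items():
        pd.DataFrame(C.values,
                     index=[f"IC{i}" for i in range(C.values.shape[0])],
                     columns=[f"network_{j + 1}" for j in range(C.values.shape[1])]
                     ).to_csv(out / f"correlation_matrix_d{d:02d}.tsv", sep="\t")
    if res.selection is not None:
        pd.DataFrame(res.selection.selected,
                     columns=["component", "network", "r_max"]
                     ).to_csv(out / "selection.tsv", sep="\t", index=False)
    if res.ic is not None:
        _write_nifti(out / "ic_maps.nii.gz", res.ic.component_maps,
                     res.ic.roi_voxel_index, grid)
        (out / "ica_fit_info.json").write_text(
            json.dumps(res.ic.fit_info, sort_keys=True, indent=2) + "\n")
    if res.fcmaps is not None:
        _write_nifti(out / "group_maps.nii.gz", res.fcmaps.group_z, brain_flat, grid)
        rows = []
        for pid, tc in res.fcmaps.stage1_timecourses.items():
            for t in range(tc.shape[0]):
                rows.append([pid, t] + tc[t].tolist())
        pd.DataFrame(rows, columns=["participant_id", "t"] +
                     [f"IC{k}" for k in range(res.fcmaps.dimension)]
                     ).to_csv(out / "stage1_timecourses.tsv", sep="\t", index=False)
    for name, df in (("region_sample", res.region_sample),
                     ("region_anova", res.region_anova),
                     ("region_contrasts", res.region_contrasts),
                     ("subfield_sample", res.subfield_sample),
                     ("subfield_anova", res.subfield_anova),
                     ("subfield_pairwise", res.subfield_pairwise),
                     ("subfield_ranking", res.subfield_ranking)):
        if df is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)

    provenance = {
        "package_version": _pkg_version,
        "numpy": np.__version__,
        "config_hash": config.config_hash(),
        "cohort_seed": cohort.config.seed,
        "ica_seed": config.ica_seed,
        "d_star": res.optimal.d_star,
        "notes": res.notes,
    }
    (out / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=2) + "\n")
    return out


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def _fmt_table(df: pd.DataFrame) -> str:
    return df.to_string(index=False, float_format=lambda v: f"{v:.2f}")


def write_report(run_dir: str | Path) -> Path:
    """Render the summary tables of a completed run into ``report.md``."""
    run_dir = Path(run_dir)
    needed = ["counts_by_dimension.tsv", "provenance.json"]
    missing = [n for n in needed if not (run_dir / n).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")
    prov = json.loads((run_dir / "provenance.json").read_text())
    d_star = prov["d_star"]
    lines = ["# srICA pipeline report", "",
             f"Optimal dimension: **{d_star}**", ""]

    counts = pd.read_csv(run_dir / "counts_by_dimension.tsv", sep="\t")
    lines += ["## Matched components per dimension", "", _fmt_table(counts), ""]

    cpath = run_dir / f"correlation_matrix_d{d_star:02d}.tsv"
    if cpath.exists():
        C = pd.read_csv(cpath, sep="\t", index_col=0)
        lines += [f"## Correlations of FC maps with reference networks (d = {d_star})",
                  "", _fmt_table(C.T.reset_index(names="network")), ""]

    sel_path = run_dir / "selection.tsv"
    if sel_path.exists() and len(pd.read_csv(sel_path, sep="\t")) > 0:
        sel = pd.read_csv(sel_path, sep="\t")
        lines += ["## Selected components", "", _fmt_table(sel), ""]
    else:
        lines += ["## Selected components", "", "No components matched any "
                  "reference network.", ""]

    rc = run_dir / "region_contrasts.tsv"
    if rc.exists():
        df = pd.read_csv(rc, sep="\t")
        for f in sorted(df["fc_map"].unique()):
            sub = df[df["fc_map"] == f].sort_values("z_ratio", ascending=False)
            sub = sub[["region", "z_ratio", "p_adj"]].rename(
                columns={"region": "Region", "z_ratio": "Z-ratio", "p_adj": "p-Value"})
            sub["p-Value"] = sub["p-Value"].map(lambda p: f"{p:.2e}")
            lines += [f"## Region contrasts, FC map {f}", "", _fmt_table(sub), ""]

    rk = run_dir / "subfield_ranking.tsv"
    if rk.exists():
        df = pd.read_csv(rk, sep="\t")
        tbl = df.rename(columns={"subfield": "Subnucleus", "fc_map": "IC",
                                 "summed_z_ratio": "Summed z-ratio",
                                 "rank": "Rank"})[
            ["Subnucleus", "IC", "Summed z-ratio", "Rank"]]
        tbl["Rank"] = tbl["Rank"].map(
            lambda r: str(int(r)) if pd.notna(r) else "-")
        lines += ["## Subfield contribution ranking", "", _fmt_table(tbl), ""]

    path = run_dir / "report.md"
    path.write_text("\n".join(lines))
    return path
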