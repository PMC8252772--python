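"""Synthetic resting-state cohorts with known ground truth.

Generates desk-scale 4D BOLD-like data in which two spatial sources live at
distinct positions along the long axis of a bilateral, hippocampus-like ROI.
Each source has its own subfield weight profile and is temporally coupled to
one reference-network template, so every downstream stage (spatially
restricted group ICA, dual regression, network matching, region statistics,
subfield ranking) can be validated against a known answer without any
external download.

Geometry: two mirrored curved tubes stand in for the bilateral hippocampi.
The long axis runs along the second (y) voxel axis; the 3x3 cross-section
holds six stacked subfield layers (CA1, CA3, CA4, DG, SUB) around a central
molecular layer (ML), so ML touches almost every other subfield, mirroring
its anatomical role. Subfield layout is constant along the axis.

Voxel linearization: every flat index in this package refers to C-order
(axis-major, ``numpy.ravel`` order) positions on the 3D grid. Bold4D columns
are the brain-mask voxels in ascending C-order flat index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "VolumeGrid",
    "Anatomy",
    "GroundTruth",
    "Bold4D",
    "CohortConfig",
    "Cohort",
    "SizingError",
    "SUBFIELD_NAMES",
    "HEMI_CODE_OFFSET",
    "build_anatomy",
    "simulate_participant",
    "generate_cohort",
    "load_cohort",
]

#: label code -> subfield name (order of the 6-vector weight profiles)
SUBFIELD_NAMES = {1: "CA1", 2: "CA3", 3: "CA4", 4: "DG", 5: "SUB", 6: "ML"}

#: atlas codes in the right hemisphere are region_code + HEMI_CODE_OFFSET
HEMI_CODE_OFFSET = 1000

#: minimum voxels per subfield label per hemisphere (anatomy invariant)
MIN_SUBFIELD_VOXELS = 4

_MIN_AXIS = 20  # smallest grid axis that can host the bilateral ROI tubes


class SizingError(ValueError):
    """Grid too small to host the requested anatomy."""


@dataclass(frozen=True)
class VolumeGrid:
    """Common isotropic voxel lattice for all volumes in a cohort."""

    shape: tuple[int, int, int]
    voxel_size_mm: float = 1.6

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 8 for s in self.shape):
            raise ValueError(f"grid shape must be 3 axes of >= 8 voxels, got {self.shape}")
        if int(np.prod(self.shape)) > 10**6:
            raise ValueError(f"grid {self.shape} exceeds 10^6 voxels")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def affine(self) -> np.ndarray:
        """NIfTI affine: isotropic scaling, origin at the volume center."""
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.asarray(self.shape) - 1) / 2.0 * self.voxel_size_mm
        return aff

    def flat_indices(self, mask: np.ndarray) -> np.ndarray:
        """C-order flat indices of the nonzero voxels of ``mask``."""
        if mask.shape != self.shape:
            raise ValueError(f"mask shape {mask.shape} != grid shape {self.shape}")
        return np.flatnonzero(np.ascontiguousarray(mask))

    def left_hemisphere_mask(self) -> np.ndarray:
        """Boolean volume, True where the voxel lies in the left half (low x)."""
        x = np.arange(self.shape[0])
        return (x < self.shape[0] / 2)[:, None, None] & np.ones(self.shape, dtype=bool)


@dataclass
class Anatomy:
    """Template label volumes shared by a cohort (all on one grid)."""

    grid: VolumeGrid
    brain_mask: np.ndarray          # 0/1 int16
    roi_mask: np.ndarray            # 0/1 int16, bilateral tubes
    subfields: np.ndarray           # 0..6 int16 (codes per SUBFIELD_NAMES)
    atlas: np.ndarray               # int16; left r in 1..R, right r + HEMI_CODE_OFFSET
    networks: list[np.ndarray]      # m float32 maps, each a union of atlas parcels
    nuisance_masks: dict[str, np.ndarray]  # {"csf": ..., "wm": ...}
    n_regions: int
    n_networks: int
    roi_axis_fraction: np.ndarray = field(repr=False, default=None)
    # roi_axis_fraction: float volume, fractional long-axis position (0 anterior
    # .. 1 posterior) inside the ROI, nan elsewhere

    def validate(self) -> None:
        g = self.grid.shape
        for name in ("brain_mask", "roi_mask", "subfields", "atlas"):
            if getattr(self, name).shape != g:
                raise ValueError(f"{name} not on grid {g}")
        if np.any((self.subfields > 0) & (self.roi_mask == 0)):
            raise ValueError("subfields extend outside the ROI mask")
        if np.any((self.roi_mask > 0) & (self.brain_mask == 0)):
            raise ValueError("ROI extends outside the brain mask")
        left = self.grid.left_hemisphere_mask()
        for code in SUBFIELD_NAMES:
            for hemi in (left, ~left):
                n = int(np.sum((self.subfields == code) & hemi & (self.roi_mask > 0)))
                if n < MIN_SUBFIELD_VOXELS:
                    raise ValueError(
                        f"subfield {SUBFIELD_NAMES[code]} has {n} voxels in one "
                        f"hemisphere (< {MIN_SUBFIELD_VOXELS})"
                    )
        for k, net in enumerate(self.networks):
            if np.any((net != 0) & (self.brain_mask == 0)):
                raise ValueError(f"network {k} is nonzero outside the brain mask")


@dataclass
class GroundTruth:
    """The embedded sources and amplitudes the simulation plants.

    ``subfield_weights`` rows follow the SUBFIELD_NAMES code order
    (CA1, CA3, CA4, DG, SUB, ML). Source A sits anteriorly and loads on
    CA1/CA3 (with CA4/DG support); source B spans the mid-to-posterior axis
    and loads on SUB (with CA4/DG support). ML is never a driver: it only
    receives a small bleed-over weight.
    """

    n_sources: int = 2
    hotspot_centers: tuple[float, ...] = (0.2, 0.7)
    hotspot_widths: tuple[float, ...] = (0.12, 0.18)
    subfield_weights: tuple[tuple[float, ...], ...] = (
        (1.0, 1.0, 0.6, 0.6, 0.1, 0.3),   # source A: CA1/CA3 high, SUB low
        (0.1, 0.1, 0.6, 0.6, 1.0, 0.3),   # source B: SUB high, CA1/CA3 low
    )
    network_assignment: tuple[int, ...] = (1, 6)  # 0-based template indices
    amplitude: float = 1.0
    network_leak: float = 0.6        # source weight on its network's parcels
    hemi_offset: float = 0.1         # +10% left-hemisphere gain
    participant_offset_sd: float = 0.1
    participant_offsets: dict[str, float] = field(default_factory=dict)
    snr: float = 0.7                 # source amplitude / total noise sd
    ar_coef: float = 0.3
    nuisance_amplitude: float = 1.0
    nuisance_leak: float = 0.05

    def __post_init__(self) -> None:
        if len(set(self.network_assignment)) != len(self.network_assignment):
            raise ValueError("network_assignment must be injective")
        for w in self.subfield_weights:
            if any(x < 0 for x in w):
                raise ValueError("subfield weights must be nonnegative")

    def weight_field(self, anatomy: Anatomy, source: int) -> np.ndarray:
        """Whole-grid weight volume for one source (before hemisphere gain)."""
        w = np.zeros(anatomy.grid.shape, dtype=np.float64)
        roi = anatomy.roi_mask > 0
        frac = anatomy.roi_axis_fraction
        c, s = self.hotspot_centers[source], self.hotspot_widths[source]
        profile = np.exp(-0.5 * ((frac[roi] - c) / s) ** 2)
        sub_w = np.zeros(7)
        sub_w[1:] = self.subfield_weights[source]
        w[roi] = profile * sub_w[anatomy.subfields[roi]]
        net = anatomy.networks[self.network_assignment[source]]
        outside = ~roi
        w[outside] += self.network_leak * net[outside]
        return w


@dataclass
class Bold4D:
    """One participant-run's time x voxel data on the common grid.

    ``data`` columns are the brain-mask voxels in C-order flat-index order;
    ``voxel_index`` maps each column to its flat grid index.
    """

    participant_id: str
    run_id: str
    data: np.ndarray                 # T x V_brain
    grid: VolumeGrid
    voxel_index: np.ndarray          # V_brain flat C-order grid indices

    def __post_init__(self) -> None:
        if self.data.shape[0] < 30:
            raise ValueError(f"need T >= 30 volumes, got {self.data.shape[0]}")
        if self.data.shape[1] != len(self.voxel_index):
            raise ValueError("data columns do not match voxel_index")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Bold4D contains non-finite values")

    @property
    def n_timepoints(self) -> int:
        return int(self.data.shape[0])

    def to_volume(self, row: int | None = None) -> np.ndarray:
        """Scatter one timepoint (or the temporal mean) back onto the grid."""
        vec = self.data[row] if row is not None else self.data.mean(axis=0)
        vol = np.zeros(self.grid.n_voxels, dtype=np.float32)
        vol[self.voxel_index] = vec
        return vol.reshape(self.grid.shape)


# ---------------------------------------------------------------------------
# anatomy construction
# ---------------------------------------------------------------------------

# 3x3 cross-section (dx, dz) -> subfield code; ML central, flanked by the rest
_CROSS_SECTION = {
    (-1, -1): 1, (0, -1): 1, (1, -1): 2,
    (-1, 0): 5, (0, 0): 6, (1, 0): 2,
    (-1, 1): 5, (0, 1): 4, (1, 1): 3,
}


def _tube_centerline(grid: VolumeGrid, hemisphere: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Voxel coordinates of the curved tube center per axial slice."""
    nx, ny, nz = grid.shape
    y0, y1 = int(round(0.2 * ny)), int(round(0.8 * ny))
    ys = np.arange(y0, y1)
    t = (ys - y0) / max(len(ys) - 1, 1)
    # bow in z gives the "curved tube"; mirrored x for the two hemispheres
    zc = np.round(nz / 2 + 1.5 * np.sin(np.pi * t)).astype(int)
    x_right = int(round(0.70 * nx))
    xc = np.full_like(ys, x_right if hemisphere == "R" else nx - 1 - x_right)
    return xc, ys, zc


def build_anatomy(grid: VolumeGrid, r_regions: int = 42, m_networks: int = 7,
                  seed: int = 0) -> Anatomy:
    """Build the template anatomy: brain sphere, bilateral ROI tubes with six
    subfield layers, a bilateral k-means parcellation with ``r_regions``
    regions per hemisphere, ``m_networks`` network templates (unions of
    parcels), and CSF-/WM-like nuisance masks. Deterministic given ``seed``.
    """
    if not (r_regions >= m_networks >= 2):
        raise ValueError(f"need r_regions >= m_networks >= 2, got R={r_regions}, m={m_networks}")
    nx, ny, nz = grid.shape
    if min(grid.shape) < _MIN_AXIS:
        raise SizingError(
            f"grid {grid.shape} too small for bilateral ROI tubes with six "
            f"subfield layers; minimum shape is ({_MIN_AXIS}, {_MIN_AXIS}, {_MIN_AXIS})"
        )

    center = (np.asarray(grid.shape) - 1) / 2.0
    ii = np.indices(grid.shape, dtype=np.float64)
    dist = np.sqrt(sum((ii[a] - center[a]) ** 2 for a in range(3)))
    brain = (dist <= min(grid.shape) / 2.0 - 1.0).astype(np.int16)

    roi = np.zeros(grid.shape, dtype=np.int16)
    subf = np.zeros(grid.shape, dtype=np.int16)
    axis_frac = np.full(grid.shape, np.nan)
    for hemi in ("L", "R"):
        xc, ys, zc = _tube_centerline(grid, hemi)
        t = (ys - ys[0]) / max(len(ys) - 1, 1)
        for (dx, dz), code in _CROSS_SECTION.items():
            dxh = dx if hemi == "R" else -dx  # mirror the cross-section
            xs, zs = xc + dxh, zc + dz
            roi[xs, ys, zs] = 1
            subf[xs, ys, zs] = code
            axis_frac[xs, ys, zs] = t
    if np.any((roi > 0) & (brain == 0)):
        raise SizingError(f"ROI tubes fall outside the brain mask on grid {grid.shape}")

    csf = ((dist <= 1.8) & (roi == 0)).astype(np.int16)
    wm = ((dist > 2.2) & (dist <= 3.4) & (roi == 0) & (csf == 0)).astype(np.int16)

    free = (brain > 0) & (roi == 0) & (csf == 0) & (wm == 0)
    left = grid.left_hemisphere_mask()
    left_vox = np.argwhere(free & left)
    if len(left_vox) < 2 * r_regions:
        raise SizingError(
            f"only {len(left_vox)} free voxels per hemisphere for {r_regions} "
            f"parcels; enlarge the grid"
        )

    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=r_regions, n_init=1, random_state=int(seed) % (2**31))
    lab = km.fit_predict(left_vox.astype(np.float64))
    # relabel deterministically by centroid lexicographic order -> codes 1..R
    order = np.lexsort(km.cluster_centers_.T[::-1])
    remap = np.empty(r_regions, dtype=np.int16)
    remap[order] = np.arange(1, r_regions + 1)
    atlas = np.zeros(grid.shape, dtype=np.int16)
    atlas[tuple(left_vox.T)] = remap[lab]
    # mirror the left parcellation onto the right hemisphere (bilateral atlas)
    mirrored = atlas[::-1, :, :].copy()
    right_free = free & ~left
    atlas[right_free] = mirrored[right_free] + HEMI_CODE_OFFSET
    # any right voxel whose mirror was unlabeled: nearest labeled mirror parcel
    missing = right_free & (atlas == HEMI_CODE_OFFSET)
    if np.any(missing):
        from scipy.spatial import cKDTree

        lab_r = np.argwhere(right_free & (atlas > HEMI_CODE_OFFSET))
        tree = cKDTree(lab_r)
        mv = np.argwhere(missing)
        _, nn = tree.query(mv)
        atlas[tuple(mv.T)] = atlas[tuple(lab_r[nn].T)]

    # networks: contiguous blocks of region codes, bilateral binary maps
    bounds = np.linspace(0, r_regions, m_networks + 1).round().astype(int)
    networks = []
    code = atlas % HEMI_CODE_OFFSET
    code[atlas == 0] = 0
    for j in range(m_networks):
        lo, hi = bounds[j] + 1, bounds[j + 1]
        net = ((code >= lo) & (code <= hi) & (atlas > 0)).astype(np.float32)
        networks.append(net)

    anatomy = Anatomy(
        grid=grid, brain_mask=brain, roi_mask=roi, subfields=subf, atlas=atlas,
        networks=networks, nuisance_masks={"csf": csf, "wm": wm},
        n_regions=r_regions, n_networks=m_networks, roi_axis_fraction=axis_frac,
    )
    anatomy.validate()
    return anatomy


def jitter_labels(labels: np.ndarray, rng: np.random.Generator, p: float = 0.2,
                  min_count: int = MIN_SUBFIELD_VOXELS,
                  hemi_mask: np.ndarray | None = None) -> np.ndarray:
    """Morphological boundary jitter: reassign a random subset of boundary
    voxels to a neighboring label (<= 1 voxel displacement). Never moves the
    mask support, only internal label boundaries; keeps every (label,
    hemisphere) count at or above ``min_count``.
    """
    out = labels.copy()
    shape = labels.shape
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    neigh = []
    for o in offs:
        shifted = np.roll(out, shift=o, axis=(0, 1, 2))
        neigh.append(shifted)
    neigh = np.stack(neigh)  # 6 x shape
    inside = out > 0
    differs = (neigh != out[None]) & (neigh > 0) & inside[None]
    boundary = np.argwhere(differs.any(axis=0))
    if len(boundary) == 0:
        return out
    pick = boundary[rng.random(len(boundary)) < p]
    rng.shuffle(pick)

    def key(vox, lab):
        if hemi_mask is None:
            return int(lab)
        return (int(lab), bool(hemi_mask[tuple(vox)]))

    counts: dict = {}
    labs, cts = np.unique(out[inside], return_counts=True)
    if hemi_mask is None:
        counts = dict(zip(labs.tolist(), cts.tolist()))
    else:
        for lb in labs:
            counts[(int(lb), True)] = int(np.sum((out == lb) & hemi_mask))
            counts[(int(lb), False)] = int(np.sum((out == lb) & ~hemi_mask))
    for vox in pick:
        vox_t = tuple(vox)
        cur = out[vox_t]
        k = key(vox, cur)
        if counts[k] <= min_count:
            continue
        cands = []
        for o in offs:
            nb = tuple((vox + o) % shape)  # labels never touch the grid edge
            lb = labels[nb]  # candidates from the original volume: <= 1 voxel move
            if lb > 0 and lb != cur:
                cands.append(int(lb))
        if not cands:
            continue
        new = cands[int(rng.integers(len(cands)))]
        out[vox_t] = new
        counts[k] -= 1
        nk = key(vox, new)
        counts[nk] = counts.get(nk, 0) + 1
    return out


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def _ar1_noise(rng: np.random.Generator, T: int, V: int, sd: float,
               ar_coef: float) -> np.ndarray:
    """AR(1) process plus white noise, total stationary sd ``sd``."""
    if sd == 0:
        return np.zeros((T, V))
    sd_part = sd / np.sqrt(2.0)
    innov_sd = sd_part * np.sqrt(1.0 - ar_coef**2)
    ar = lfilter([1.0], [1.0, -ar_coef], rng.normal(0.0, innov_sd, (T, V)), axis=0)
    return ar + rng.normal(0.0, sd_part, (T, V))


def simulate_participant(anatomy: Anatomy, truth: GroundTruth, participant_id: str,
                         run_id: str, T: int = 200, seed: int = 0) -> Bold4D:
    """Simulate one run: summed source signals with hemisphere gain, CSF/WM
    nuisance signals (leaked weakly brain-wide), and AR(1)-plus-white noise.
    Deterministic given ``seed``. The spatial weight field is a pure function
    of (anatomy, truth); only time courses and noise depend on the run seed.
    """
    if T < 30:
        raise ValueError(f"need T >= 30 (downstream regressions are ill-posed), got T={T}")
    for s in range(truth.n_sources):
        if truth.network_assignment[s] >= len(anatomy.networks):
            raise ValueError(f"network index {truth.network_assignment[s]} out of range")
    rng = np.random.default_rng(seed)
    vox = anatomy.grid.flat_indices(anatomy.brain_mask)
    V = len(vox)

    amp = truth.amplitude * (1.0 + truth.participant_offsets.get(participant_id, 0.0))
    gain = np.ones(anatomy.grid.n_voxels)
    gain[anatomy.grid.flat_indices(anatomy.grid.left_hemisphere_mask())] *= 1.0 + truth.hemi_offset
    data = np.zeros((T, V))
    x = rng.standard_normal((truth.n_sources, T))
    if amp != 0:
        for s in range(truth.n_sources):
            w = truth.weight_field(anatomy, s).ravel() * gain
            data += np.outer(x[s], amp * w[vox])

    nuis = rng.standard_normal((2, T))
    leak = np.full(V, truth.nuisance_leak)
    for k, name in enumerate(("csf", "wm")):
        m = anatomy.nuisance_masks[name].ravel()[vox] > 0
        load = leak.copy()
        load[m] = truth.nuisance_amplitude
        data += np.outer(nuis[k], load)

    noise_sd = 0.0 if np.isinf(truth.snr) else (
        truth.amplitude / truth.snr if truth.amplitude > 0 else 1.0 / truth.snr)
    data += _ar1_noise(rng, T, V, noise_sd, truth.ar_coef)
    return Bold4D(participant_id=participant_id, run_id=run_id,
                  data=data.astype(np.float32), grid=anatomy.grid, voxel_index=vox)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------


@dataclass
class CohortConfig:
    n_participants: int = 20
    n_runs: int = 2
    n_timepoints: int = 200
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.6
    r_regions: int = 42
    m_networks: int = 7
    amplitude: float = 1.0
    snr: float = 0.7
    jitter: bool = True
    jitter_p: float = 0.2
    seed: int = 0
    out_dir: str | None = None

    def make_grid(self) -> VolumeGrid:
        return VolumeGrid(tuple(self.grid_shape), self.voxel_size_mm)


@dataclass
class Cohort:
    config: CohortConfig
    template: Anatomy
    participant_anatomy: dict[str, Anatomy]
    runs: list[Bold4D]
    truth: GroundTruth
    manifest: dict

    @property
    def participant_ids(self) -> list[str]:
        return sorted(self.participant_anatomy)

    def runs_for(self, pid: str) -> list[Bold4D]:
        return [b for b in self.runs if b.participant_id == pid]


def generate_cohort(config: CohortConfig, truth: GroundTruth | None = None) -> Cohort:
    """Generate a full cohort: template anatomy, per-participant jittered
    labels, N x runs Bold4D datasets, and the serialized ground truth.
    If ``config.out_dir`` is set, NIfTI volumes plus a JSON manifest and
    ground-truth file are written there. Pure function of (config, truth).
    """
    grid = config.make_grid()
    root = np.random.SeedSequence(config.seed)
    anat_seed, jit_seed, off_seed, run_root = root.spawn(4)
    anatomy = build_anatomy(grid, config.r_regions, config.m_networks,
                            seed=int(anat_seed.generate_state(1)[0] % 2**31))
    if truth is None:
        truth = GroundTruth(amplitude=config.amplitude, snr=config.snr)
    for s in range(truth.n_sources):
        if truth.network_assignment[s] >= config.m_networks:
            raise ValueError("ground-truth network index exceeds m_networks")

    pids = [f"sub-{i + 1:03d}" for i in range(config.n_participants)]
    off_rng = np.random.default_rng(off_seed)
    offsets = {pid: float(off_rng.normal(0.0, truth.participant_offset_sd)) for pid in pids}
    truth = replace(truth, participant_offsets=offsets)

    jit_rng = np.random.default_rng(jit_seed)
    left = grid.left_hemisphere_mask()
    participant_anatomy: dict[str, Anatomy] = {}
    for pid in pids:
        if config.jitter:
            subf = jitter_labels(anatomy.subfields, jit_rng, p=config.jitter_p,
                                 min_count=MIN_SUBFIELD_VOXELS, hemi_mask=left)
            atl = jitter_labels(anatomy.atlas, jit_rng, p=config.jitter_p, min_count=2)
        else:
            subf, atl = anatomy.subfields.copy(), anatomy.atlas.copy()
        participant_anatomy[pid] = replace(anatomy, subfields=subf, atlas=atl)

    run_rng = np.random.default_rng(run_root)
    runs: list[Bold4D] = []
    seed_registry: dict[str, int] = {}
    for pid in pids:
        for r in range(config.n_runs):
            rid = f"run-{r + 1}"
            s = int(run_rng.integers(2**31))
            seed_registry[f"{pid}_{rid}"] = s
            runs.append(simulate_participant(anatomy, truth, pid, rid,
                                             T=config.n_timepoints, seed=s))

    manifest = {
        "config": asdict(config),
        "participants": pids,
        "runs": [{"participant_id": b.participant_id, "run_id": b.run_id,
                  "n_timepoints": b.n_timepoints,
                  "seed": seed_registry[f"{b.participant_id}_{b.run_id}"],
                  "path": f"{b.participant_id}_{b.run_id}_bold.nii.gz"}
                 for b in runs],
        "seed_registry": seed_registry,
        "grid": {"shape": list(grid.shape), "voxel_size_mm": grid.voxel_size_mm},
    }
    cohort = Cohort(config=config, template=anatomy,
                    participant_anatomy=participant_anatomy, runs=runs,
                    truth=truth, manifest=manifest)
    if config.out_dir is not None:
        _write_cohort(cohort, Path(config.out_dir))
    return cohort


def _truth_to_json(truth: GroundTruth) -> dict:
    d = asdict(truth)
    d["snr"] = "inf" if np.isinf(truth.snr) else truth.snr
    return d


def _write_cohort(cohort: Cohort, out: Path) -> None:
    import nibabel as nib

    out.mkdir(parents=True, exist_ok=True)
    grid = cohort.template.grid
    aff = grid.affine()

    def save_label(vol, name):
        nib.save(nib.Nifti1Image(vol.astype(np.int16), aff), out / name)

    save_label(cohort.template.brain_mask, "template_brain_mask.nii.gz")
    save_label(cohort.template.roi_mask, "template_roi_mask.nii.gz")
    save_label(cohort.template.subfields, "template_subfields.nii.gz")
    save_label(cohort.template.atlas, "template_atlas.nii.gz")
    for k, name in enumerate(("csf", "wm")):
        save_label(cohort.template.nuisance_masks[name], f"template_{name}_mask.nii.gz")
    nets = np.stack(cohort.template.networks, axis=-1).astype(np.float32)
    nib.save(nib.Nifti1Image(nets, aff), out / "template_networks.nii.gz")
    for pid, an in cohort.participant_anatomy.items():
        save_label(an.subfields, f"{pid}_subfields.nii.gz")
        save_label(an.atlas, f"{pid}_atlas.nii.gz")
    for b in cohort.runs:
        vol4 = np.zeros((grid.n_voxels, b.n_timepoints), dtype=np.float32)
        vol4[b.voxel_index] = b.data.T
        img = nib.Nifti1Image(vol4.reshape(*grid.shape, b.n_timepoints), aff)
        nib.save(img, out / f"{b.participant_id}_{b.run_id}_bold.nii.gz")
    (out / "manifest.json").write_text(
        json.dumps(cohort.manifest, sort_keys=True, indent=2) + "\n")
    (out / "ground_truth.json").write_text(
        json.dumps(_truth_to_json(cohort.truth), sort_keys=True, indent=2) + "\n")


def load_cohort(manifest_path: str | Path) -> Cohort:
    """Rebuild a cohort from a directory written by :func:`generate_cohort`.

    Volumes are reloaded from NIfTI; the template anatomy is regenerated from
    the recorded config (deterministic), then overridden with the stored
    per-participant label volumes.
    """
    import nibabel as nib

    manifest_path = Path(manifest_path)
    root = manifest_path.parent if manifest_path.is_file() else manifest_path
    manifest = json.loads((root / "manifest.json").read_text())
    cfg_d = dict(manifest["config"])
    cfg_d["grid_shape"] = tuple(cfg_d["grid_shape"])
    cfg_d["out_dir"] = None
    config = CohortConfig(**cfg_d)
    truth_d = json.loads((root / "ground_truth.json").read_text())
    if truth_d.get("snr") == "inf":
        truth_d["snr"] = np.inf
    for key in ("hotspot_centers", "hotspot_widths", "network_assignment"):
        truth_d[key] = tuple(truth_d[key])
    truth_d["subfield_weights"] = tuple(tuple(w) for w in truth_d["subfield_weights"])
    truth = GroundTruth(**truth_d)

    grid = config.make_grid()
    seq = np.random.SeedSequence(config.seed).spawn(4)[0]
    anatomy = build_anatomy(grid, config.r_regions, config.m_networks,
                            seed=int(seq.generate_state(1)[0] % 2**31))
    participant_anatomy = {}
    for pid in manifest["participants"]:
        subf = np.asarray(nib.load(root / f"{pid}_subfields.nii.gz").dataobj, dtype=np.int16)
        atl = np.asarray(nib.load(root / f"{pid}_atlas.nii.gz").dataobj, dtype=np.int16)
        participant_anatomy[pid] = replace(anatomy, subfields=subf, atlas=atl)
    vox = grid.flat_indices(anatomy.brain_mask)
    runs = []
    for rec in manifest["runs"]:
        img = nib.load(root / rec["path"])
        arr = np.asarray(img.dataobj, dtype=np.float32).reshape(grid.n_voxels, -1)
        runs.append(Bold4D(participant_id=rec["participant_id"], run_id=rec["run_id"],
                           data=arr[vox].T.copy(), grid=grid, voxel_index=vox))
    return Cohort(config=config, template=anatomy,
                  participant_anatomy=participant_anatomy, runs=runs,
                  truth=truth, manifest=manifest)
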