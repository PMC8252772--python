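import numpy as np
import pytest

from srica import (Anatomy, Bold4D, CohortConfig, GroundTruth, VolumeGrid,
                   build_anatomy, generate_cohort)


@pytest.fixture(scope="session")
def grid():
    return VolumeGrid((24, 24, 24))


@pytest.fixture(scope="session")
def anatomy(grid) -> Anatomy:
    # small atlas keeps unit tests fast; networks still cover 7 templates
    return build_anatomy(grid, r_regions=10, m_networks=7, seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """4 participants x 2 short runs; enough signal for end-to-end checks."""
    cfg = CohortConfig(n_participants=4, n_runs=2, n_timepoints=80,
                       r_regions=10, m_networks=7, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_source_truth(**overrides) -> GroundTruth:
    """One-source ground truth used by noiseless-limit oracles."""
    kw = dict(n_sources=1, hotspot_centers=(0.3,), hotspot_widths=(0.15,),
              subfield_weights=((1.0, 0.8, 0.6, 0.5, 0.4, 0.3),),
              network_assignment=(2,), amplitude=1.0, snr=np.inf,
              nuisance_amplitude=0.0, nuisance_leak=0.0,
              participant_offset_sd=0.0, hemi_offset=0.0)
    kw.update(overrides)
    return GroundTruth(**kw)


def make_bold(grid: VolumeGrid, mask: np.ndarray, data: np.ndarray,
              pid: str = "sub-001", run: str = "run-1") -> Bold4D:
    return Bold4D(participant_id=pid, run_id=run, data=data, grid=grid,
                  voxel_index=grid.flat_indices(mask))
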