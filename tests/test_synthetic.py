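"""Anatomy construction, simulation physics, and cohort assembly."""

import json

import numpy as np
import pytest

from srica import (CohortConfig, GroundTruth, SizingError, SUBFIELD_NAMES,
                   VolumeGrid, build_anatomy, generate_cohort, load_cohort,
                   simulate_participant)
from srica.synthetic import jitter_labels

from conftest import single_source_truth


class TestBuildAnatomy:
    def test_invariants_hold(self, grid):
        an = build_anatomy(grid, r_regions=10, m_networks=3, seed=1)
        an.validate()  # raises on any violated invariant
        left = grid.left_hemisphere_mask()
        for code in SUBFIELD_NAMES:
            assert ((an.subfields == code) & left).sum() >= 4
            assert ((an.subfields == code) & ~left).sum() >= 4
        # atlas regions pairwise disjoint by construction (single label volume);
        # each bilateral region code present in both hemispheres
        codes = np.unique(an.atlas[an.atlas > 0])
        lefts = {c for c in codes if c < 1000}
        rights = {c - 1000 for c in codes if c > 1000}
        assert lefts == rights == set(range(1, 11))

    def test_deterministic(self, grid):
        a = build_anatomy(grid, 10, 3, seed=5)
        b = build_anatomy(grid, 10, 3, seed=5)
        for name in ("brain_mask", "roi_mask", "subfields", "atlas"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(SizingError, match="minimum shape"):
            build_anatomy(VolumeGrid((8, 8, 8)), r_regions=42, m_networks=7)

    def test_networks_are_parcel_unions_inside_brain(self, anatomy):
        for net in anatomy.networks:
            assert not np.any((net != 0) & (anatomy.brain_mask == 0))
            assert net.sum() > 0

    def test_requires_more_regions_than_networks(self, grid):
        with pytest.raises(ValueError, match="r_regions >= m_networks"):
            build_anatomy(grid, r_regions=2, m_networks=3)


class TestSimulateParticipant:
    def test_noiseless_single_source_is_proportional_to_timecourse(self, anatomy):
        truth = single_source_truth()
        bold = simulate_participant(anatomy, truth, "p", "r", T=60, seed=2)
        w = truth.weight_field(anatomy, 0).ravel()[bold.voxel_index]
        active = w > 1e-6
        # every active voxel's series correlates perfectly with the source
        ref = bold.data[:, np.argmax(w)]
        r = np.corrcoef(bold.data[:, active].T, ref)[-1, :-1]
        assert np.all(np.abs(r) > 1 - 1e-10)

    def test_null_amplitude_has_no_roi_network_coupling(self, anatomy):
        """With amplitude 0 only nuisance + noise remain; after nuisance
        regression the ROI and network mean series are uncoupled."""
        from srica import preprocess_run

        rs = []
        truth = GroundTruth(amplitude=0.0)
        roi = anatomy.roi_mask.ravel()
        net = anatomy.networks[truth.network_assignment[0]].ravel()
        for seed in range(20):
            bold = simulate_participant(anatomy, truth, "p", "r", T=200, seed=seed)
            bold = preprocess_run(bold, anatomy)
            roi_series = bold.data[:, roi[bold.voxel_index] > 0].mean(axis=1)
            net_series = bold.data[:, net[bold.voxel_index] > 0].mean(axis=1)
            rs.append(np.corrcoef(roi_series, net_series)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_two_runs_share_weights_but_not_noise(self, anatomy):
        truth = GroundTruth()
        a = simulate_participant(anatomy, truth, "p", "run-1", T=40, seed=1)
        b = simulate_participant(anatomy, truth, "p", "run-2", T=40, seed=2)
        assert not np.allclose(a.data, b.data)
        np.testing.assert_array_equal(truth.weight_field(anatomy, 0),
                                      truth.weight_field(anatomy, 0))

    def test_short_run_rejected(self, anatomy):
        with pytest.raises(ValueError, match="T >= 30"):
            simulate_participant(anatomy, GroundTruth(), "p", "r", T=20, seed=0)

    def test_deterministic_given_seed(self, anatomy):
        t = GroundTruth()
        a = simulate_participant(anatomy, t, "p", "r", T=40, seed=9)
        b = simulate_participant(anatomy, t, "p", "r", T=40, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_source_weight_fields_track_long_axis(self, anatomy):
        """Source A loads anterior ROI voxels; source B posterior ones."""
        truth = GroundTruth()
        frac = anatomy.roi_axis_fraction
        roi = anatomy.roi_mask > 0
        anterior = roi & (frac < 0.5)
        posterior = roi & (frac >= 0.5)
        for s, heavy, light in ((0, anterior, posterior), (1, posterior, anterior)):
            w = truth.weight_field(anatomy, s)
            assert w[heavy].mean() > w[light].mean()


class TestGenerateCohort:
    def test_counts(self):
        cfg = CohortConfig(n_participants=3, n_runs=2, n_timepoints=40,
                           r_regions=10, m_networks=7, seed=1)
        c = generate_cohort(cfg)
        assert len(c.runs) == 6
        assert len(c.participant_anatomy) == 3
        assert len(c.truth.participant_offsets) == 3

    def test_jitter_disabled_keeps_template_labels(self):
        cfg = CohortConfig(n_participants=2, n_runs=1, n_timepoints=40,
                           r_regions=10, m_networks=7, seed=1, jitter=False)
        c = generate_cohort(cfg)
        for an in c.participant_anatomy.values():
            np.testing.assert_array_equal(an.atlas, c.template.atlas)
            np.testing.assert_array_equal(an.subfields, c.template.subfields)

    def test_jitter_moves_only_internal_boundaries(self, anatomy, rng):
        jit = jitter_labels(anatomy.subfields, rng, p=0.5,
                            hemi_mask=anatomy.grid.left_hemisphere_mask())
        assert np.array_equal(jit > 0, anatomy.subfields > 0)  # support fixed
        changed = np.argwhere(jit != anatomy.subfields)
        assert len(changed) > 0
        offs = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                         (0, 0, 1), (0, 0, -1)])
        for vox in changed:  # each new label was a 6-neighbor's template label
            neigh = [anatomy.subfields[tuple(vox + o)] for o in offs]
            assert jit[tuple(vox)] in neigh
        left = anatomy.grid.left_hemisphere_mask()
        for code in SUBFIELD_NAMES:
            assert ((jit == code) & left).sum() >= 4
            assert ((jit == code) & ~left).sum() >= 4

    def test_manifest_byte_identical_on_rerun(self, tmp_path):
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            cfg = CohortConfig(n_participants=2, n_runs=1, n_timepoints=40,
                               r_regions=10, m_networks=7, seed=4, out_dir=str(out))
            generate_cohort(cfg)
        m1 = (out1 / "manifest.json").read_bytes()
        m2 = (out2 / "manifest.json").read_bytes()
        assert m1.replace(str(out1).encode(), b"") == m2.replace(str(out2).encode(), b"")

    def test_nifti_roundtrip(self, tmp_path):
        cfg = CohortConfig(n_participants=2, n_runs=1, n_timepoints=40,
                           r_regions=10, m_networks=7, seed=4,
                           out_dir=str(tmp_path / "c"))
        c = generate_cohort(cfg)
        c2 = load_cohort(tmp_path / "c" / "manifest.json")
        assert c2.participant_ids == c.participant_ids
        np.testing.assert_allclose(c2.runs[0].data, c.runs[0].data, atol=1e-6)
        np.testing.assert_array_equal(
            c2.participant_anatomy["sub-001"].atlas,
            c.participant_anatomy["sub-001"].atlas)
        assert c2.truth.network_assignment == c.truth.network_assignment
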