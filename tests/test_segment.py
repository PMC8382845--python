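import dataclasses

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.measure import label as cc_label

from tauscreen import (
    FieldImage,
    SegmentationParams,
    SynthFieldConfig,
    close_gaps,
    detect_clumps,
    detect_nuclei,
    extract_neurite_mask,
    finalize_masks,
    generate_field,
    segment_cell_bodies,
    segment_field,
)
from tauscreen import test_neurite_segments as vet_neurite_segments
from tauscreen.errors import MaskGeometryError
from tauscreen.segment import NucleusRecord


def _uniform_field(shape=(128, 128), value=100.0):
    ch = {c: np.full(shape, value, np.float32)
          for c in ("dna", "tubulin", "total_tau", "p_tau")}
    return FieldImage("A1", 0, ch)


class TestDetectNuclei:
    def test_pure_noise_yields_no_nuclei(self, noise_field):
        field, _ = noise_field
        labels, recs = detect_nuclei(field, SegmentationParams())
        assert labels.max() == 0 and recs == []

    def test_live_and_dead_classification(self):
        cfg = SynthFieldConfig(grid_shape=(384, 384), n_neurons=10,
                               n_nonneuronal=0, n_dead=3, clump_fraction=0.0,
                               seed=21)
        field, truth = generate_field(cfg)
        labels, recs = detect_nuclei(field, SegmentationParams())
        n_live = sum(1 for r in recs if r.klass != "dead_excluded")
        n_dead = sum(1 for r in recs if r.klass == "dead_excluded")
        assert n_live == 10
        assert n_dead >= 2

    def test_small_bright_rugged_object_classed_dead(self):
        # one live-sized round nucleus plus one small, bright, spiky object
        rng = np.random.default_rng(0)
        dna = np.full((128, 128), 80.0)
        rr, cc = draw_disk((40, 40), 7, shape=dna.shape)
        dna[rr, cc] = 600.0
        from tauscreen.simulate import _rugged_polygon
        rr, cc = _rugged_polygon(np.random.default_rng(3), (90, 90), 4.5,
                                 dna.shape)
        dna[rr, cc] = 1500.0
        dna = rng.poisson(dna).astype(float)
        field = _uniform_field()
        field.channels["dna"] = dna
        labels, recs = detect_nuclei(field, SegmentationParams())
        classes = sorted(r.klass for r in recs)
        assert "dead_excluded" in classes
        dead = [r for r in recs if r.klass == "dead_excluded"]
        assert all(r.area <= 55 and r.solidity <= 0.85 for r in dead)


class TestSegmentCellBodies:
    def test_no_cytoskeletal_signal_means_nonneuronal(self):
        # nuclei exist but tubulin/total-tau show only background
        cfg = SynthFieldConfig(grid_shape=(256, 256), n_neurons=6,
                               n_nonneuronal=0, n_dead=0, seed=2)
        im = cfg.intensity_model
        im["tubulin"]["soma"] = im["tubulin"]["background"]
        im["total_tau"]["soma"] = im["total_tau"]["background"]
        field, _ = generate_field(cfg)
        params = SegmentationParams()
        labels, recs = detect_nuclei(field, params)
        soma = segment_cell_bodies(field, labels, recs, params)
        assert soma.max() == 0
        assert all(r.klass == "nonneuronal" for r in recs)

    def test_empty_label_grid(self, noise_field):
        field, _ = noise_field
        soma = segment_cell_bodies(field, np.zeros(field.shape, np.int32),
                                   [], SegmentationParams())
        assert soma.max() == 0

    def test_soma_recovery_on_simulator_field(self, default_field,
                                              default_masks):
        from tauscreen.evaluation import soma_f1
        _, truth = default_field
        assert soma_f1(default_masks, truth) >= 0.9


class TestExtractNeurites:
    def test_blank_field_empty_mask(self, noise_field):
        field, _ = noise_field
        mask = extract_neurite_mask(field, np.zeros(field.shape, np.int32),
                                    SegmentationParams())
        # false-positive bias: essentially nothing on pure noise
        assert mask.sum() <= 0.001 * mask.size

    def test_single_straight_major_neurite_recovered(self):
        cfg = SynthFieldConfig(grid_shape=(256, 256), n_neurons=1,
                               n_nonneuronal=0, n_dead=0, seed=5)
        tree = dataclasses.replace(cfg.neurite_tree, n_primary=(1, 1),
                                   curvature_sd=0.0, branch_prob=0.0,
                                   minor_fraction=0.0, crossing_prob=0.0)
        cfg = dataclasses.replace(cfg, neurite_tree=tree)
        field, truth = generate_field(cfg)
        masks = segment_field(field)
        true_quant = truth.neurite_mask & ~(truth.soma_labels > 0)
        inter = (masks.neurite_quant_mask & true_quant).sum()
        union = (masks.neurite_quant_mask | true_quant).sum()
        assert inter / union >= 0.8

    def test_one_iteration_subset_of_ten(self, default_field):
        field, _ = default_field
        p10 = SegmentationParams()
        p1 = SegmentationParams(neurite_iterations=1, cutoff_schedule=(1.0,))
        labels, recs = detect_nuclei(field, p10)
        soma = segment_cell_bodies(field, labels, recs, p10)
        m1 = extract_neurite_mask(field, soma, p1)
        m10 = extract_neurite_mask(field, soma, p10)
        assert not (m1 & ~m10).any()
        assert m10.sum() > m1.sum()

    def test_mask_grows_monotonically_with_iterations(self, default_field):
        field, _ = default_field
        params = SegmentationParams()
        labels, recs = detect_nuclei(field, params)
        soma = segment_cell_bodies(field, labels, recs, params)
        prev = None
        for n in (2, 5, 10):
            p = SegmentationParams(
                neurite_iterations=n,
                cutoff_schedule=SegmentationParams().cutoff_schedule[:n])
            m = extract_neurite_mask(field, soma, p)
            if prev is not None:
                assert not (prev & ~m).any()
            prev = m

    def test_cutoff_schedule_must_be_non_increasing(self):
        with pytest.raises(ValueError, match="non-increasing"):
            SegmentationParams(neurite_iterations=3,
                               cutoff_schedule=(0.5, 0.8, 1.0))


class TestSegmentTest:
    def _field_with_line(self, value, length=40, shape=(128, 128)):
        field = _uniform_field(shape)
        mask = np.zeros(shape, bool)
        mask[60, 10:10 + length] = True
        for c in ("tubulin", "total_tau", "p_tau"):
            field.channels[c] = np.where(mask, value,
                                         field.channels[c]).astype(np.float32)
        return field, mask

    def test_low_contrast_segment_removed(self):
        field, mask = self._field_with_line(102.0)   # 1.02x background
        out = vet_neurite_segments(mask, field, np.zeros(field.shape, np.int32),
                                    SegmentationParams())
        assert not out.any()

    def test_good_contrast_segment_retained(self):
        field, mask = self._field_with_line(200.0)   # 2x background
        out = vet_neurite_segments(mask, field, np.zeros(field.shape, np.int32),
                                    SegmentationParams())
        np.testing.assert_array_equal(out, mask)

    def test_tiny_blob_removed(self):
        field = _uniform_field()
        mask = np.zeros(field.shape, bool)
        mask[50:51, 50:52] = True
        out = vet_neurite_segments(mask, field, np.zeros(field.shape, np.int32),
                                    SegmentationParams())
        assert not out.any()

    def test_soma_touching_segment_always_kept(self):
        field, mask = self._field_with_line(102.0)
        soma = np.zeros(field.shape, np.int32)
        soma[55:65, 5:12] = 1
        out = vet_neurite_segments(mask, field, soma, SegmentationParams())
        assert out.any()


class TestCloseGaps:
    def test_collinear_gap_bridged(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 5:20] = True
        mask[25, 24:40] = True
        out = close_gaps(mask, SegmentationParams(gap_max_length=6))
        assert cc_label(out, connectivity=2).max() == 1

    def test_perpendicular_endpoints_not_bridged(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 5:20] = True
        mask[29:40, 24] = True
        out = close_gaps(mask, SegmentationParams(gap_max_length=6))
        assert cc_label(out, connectivity=2).max() == 2

    def test_gap_longer_than_limit_not_bridged(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 5:20] = True
        mask[25, 30:45] = True
        out = close_gaps(mask, SegmentationParams(gap_max_length=6))
        assert cc_label(out, connectivity=2).max() == 2

    def test_idempotent(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 5:20] = True
        mask[25, 24:40] = True
        params = SegmentationParams(gap_max_length=6)
        once = close_gaps(mask, params)
        twice = close_gaps(once, params)
        np.testing.assert_array_equal(once, twice)

    def test_connected_mask_unchanged(self):
        mask = np.zeros((50, 50), bool)
        mask[25, 5:40] = True
        out = close_gaps(mask, SegmentationParams())
        np.testing.assert_array_equal(out, mask)


class TestClumps:
    def test_isolated_nucleus_no_clump(self):
        cfg = SynthFieldConfig(grid_shape=(256, 256), n_neurons=4,
                               n_nonneuronal=0, n_dead=0, clump_fraction=0.0,
                               seed=31)
        field, _ = generate_field(cfg)
        params = SegmentationParams()
        labels, recs = detect_nuclei(field, params)
        clump = detect_clumps(field, labels, recs, params)
        assert not clump.any()

    def test_fused_clump_covered(self):
        # a five-member clump must be detected and covered >= 80%
        cfg = SynthFieldConfig(grid_shape=(384, 384), n_neurons=20,
                               n_nonneuronal=0, n_dead=0, clump_fraction=0.25,
                               seed=8)
        field, truth = generate_field(cfg)
        masks = segment_field(field)
        assert truth.clump_mask.any()
        cover = (masks.clump_mask & truth.clump_mask).sum() / truth.clump_mask.sum()
        assert cover >= 0.8

    def test_neurite_through_clump_excluded(self):
        cfg = SynthFieldConfig(grid_shape=(384, 384), n_neurons=20,
                               n_nonneuronal=0, n_dead=0, clump_fraction=0.25,
                               seed=8)
        field, truth = generate_field(cfg)
        masks = segment_field(field)
        assert not (masks.neurite_quant_mask & masks.clump_mask).any()


class TestFinalize:
    def test_disjoint_inputs_pass_through(self):
        shape = (64, 64)
        soma = np.zeros(shape, np.int32)
        rr, cc = draw_disk((20, 20), 8, shape=shape)
        soma[rr, cc] = 1
        neur = np.zeros(shape, bool)
        neur[50, 5:60] = True
        clump = np.zeros(shape, bool)
        masks = finalize_masks(np.zeros(shape, np.int32), [], soma, neur,
                               neur, clump)
        np.testing.assert_array_equal(masks.neurite_quant_mask, neur)
        np.testing.assert_array_equal(masks.soma_quant_labels, soma)

    def test_crossing_subtraction_arithmetic(self):
        shape = (64, 64)
        soma = np.zeros(shape, np.int32)
        soma[20:40, 20:40] = 1                      # 400 px square soma
        neur = np.zeros(shape, bool)
        neur[30, 5:35] = True                       # crosses 15 px of the soma
        crossing = int((neur & (soma > 0)).sum())
        masks = finalize_masks(np.zeros(shape, np.int32), [], soma, neur,
                               neur, np.zeros(shape, bool))
        assert (masks.soma_quant_labels > 0).sum() == 400 - crossing
        assert masks.neurite_quant_mask.sum() == neur.sum() - crossing

    def test_soma_inside_clump_removed(self):
        shape = (64, 64)
        soma = np.zeros(shape, np.int32)
        soma[10:20, 10:20] = 1
        clump = np.zeros(shape, bool)
        clump[5:25, 5:25] = True
        masks = finalize_masks(np.zeros(shape, np.int32), [], soma,
                               np.zeros(shape, bool), np.zeros(shape, bool),
                               clump)
        assert 1 not in np.unique(masks.soma_quant_labels)

    def test_geometry_mismatch(self):
        with pytest.raises(MaskGeometryError):
            finalize_masks(np.zeros((8, 8), np.int32), [],
                           np.zeros((8, 9), np.int32), np.zeros((8, 8), bool),
                           np.zeros((8, 8), bool), np.zeros((8, 8), bool))


class TestSegmentField:
    def test_blank_field_empty_masks(self, noise_field):
        field, _ = noise_field
        masks = segment_field(field)
        assert masks.nucleus_labels.max() == 0
        assert not masks.neurite_quant_mask.any()
        masks.validate()

    def test_deterministic(self, default_field, default_masks):
        field, _ = default_field
        again = segment_field(field, SegmentationParams())
        np.testing.assert_array_equal(again.neurite_quant_mask,
                                      default_masks.neurite_quant_mask)
        np.testing.assert_array_equal(again.soma_quant_labels,
                                      default_masks.soma_quant_labels)

    def test_compartment_disjointness(self, default_masks):
        assert not (default_masks.neurite_quant_mask
                    & (default_masks.soma_labels > 0)).any()
        assert not (default_masks.clump_mask
                    & (default_masks.soma_quant_labels > 0)).any()
        default_masks.validate()

    def test_neurite_recovery(self, default_field, default_masks):
        from tauscreen.evaluation import neurite_quant_iou
        _, truth = default_field
        assert neurite_quant_iou(default_masks, truth) >= 0.7

    def test_gain_stability_with_compensation(self, default_field,
                                              default_masks):
        # common gain on all channels, compensated by the run-level
        # adjustments, moves neurite area by < 5%
        field, _ = default_field
        for gain in (0.8, 1.25):
            scaled = FieldImage(
                field.well_id, field.field_index,
                {c: np.asarray(v, np.float64) * gain
                 for c, v in field.channels.items()})
            masks = segment_field(scaled, SegmentationParams())
            a0 = default_masks.neurite_quant_mask.sum()
            a1 = masks.neurite_quant_mask.sum()
            assert abs(a1 - a0) / a0 < 0.05

    def test_at_most_three_adjustments(self):
        with pytest.raises(ValueError, match="3 global"):
            SegmentationParams(global_intensity_adjustments={
                "a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
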