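import logging

import numpy as np
import pytest

from celloc import coloc, synthgen
from celloc.coloc import UndefinedCorrelationError
from celloc.segment import LabelMask
from celloc.synthgen import ImageStack, NoiseModel, SceneSpec

from conftest import truth_label_mask
from oracles import definitional_pearson


def small_mask(shape=(5, 5)):
    labels = np.zeros(shape, dtype=int)
    labels[1:4, 1:4] = 1
    return LabelMask(labels=labels)


class TestPearsonRoi:
    def test_identity_gives_one(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 100, (5, 5))
        mask = small_mask()
        assert coloc.pearson_roi(a, a.copy(), mask, 1) == pytest.approx(1.0)

    def test_negative_affine_gives_minus_one(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 100, (5, 5))
        b = -a + 300.0
        assert coloc.pearson_roi(a, b, small_mask(), 1) == pytest.approx(-1.0)

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 255, (5, 5))
        b = rng.uniform(0, 255, (5, 5))
        mask = small_mask()
        expected = definitional_pearson(a[mask.labels == 1],
                                        b[mask.labels == 1])
        assert coloc.pearson_roi(a, b, mask, 1) == pytest.approx(
            expected, rel=1e-12)

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 255, (5, 5))
        b = rng.uniform(0, 255, (5, 5))
        mask = small_mask()
        r0 = coloc.pearson_roi(a, b, mask, 1)
        r1 = coloc.pearson_roi(3.7 * a + 11.0, 0.2 * b + 90.0, mask, 1)
        assert r1 == pytest.approx(r0, rel=1e-11)

    def test_depends_only_on_roi_pixels(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(0, 255, (5, 5))
        b = rng.uniform(0, 255, (5, 5))
        mask = small_mask()
        r0 = coloc.pearson_roi(a, b, mask, 1)
        b2 = b.copy()
        b2[mask.labels == 0] = 9999.0
        assert coloc.pearson_roi(a, b2, mask, 1) == r0

    def test_constant_channel_raises(self):
        a = np.arange(25.0).reshape(5, 5)
        b = np.full((5, 5), 3.0)
        with pytest.raises(UndefinedCorrelationError):
            coloc.pearson_roi(a, b, small_mask(), 1)

    def test_missing_label_raises(self):
        a = np.arange(25.0).reshape(5, 5)
        with pytest.raises(ValueError):
            coloc.pearson_roi(a, a, small_mask(), 99)


def _toy_stack(labels, rng, genotype="G", image_id="img0"):
    shape = labels.shape
    chans = {"protein": rng.uniform(0, 100, shape),
             "comarker": rng.uniform(0, 100, shape),
             "nuclei": np.zeros(shape)}
    stack = ImageStack(channels=chans, genotype_label=genotype, comarker="PM")
    stack.image_id = image_id
    return stack


class TestMeasureDataset:
    def test_record_counting_and_sorting(self):
        rng = np.random.default_rng(0)
        labels = np.zeros((20, 20), dtype=int)
        labels[1:5, 1:5] = 1
        labels[8:12, 8:12] = 2
        labels[15:19, 15:19] = 3
        mask = LabelMask(labels=labels)
        stacks = [_toy_stack(labels, rng, "B", "i1"),
                  _toy_stack(labels, rng, "A", "i0")]
        records = coloc.measure_dataset(stacks, [mask, mask])
        assert len(records) == 6
        keys = [(r.genotype_label, r.image_id, r.cell_label) for r in records]
        assert keys == sorted(keys)
        assert all(r.n_pixels == 16 for r in records)

    def test_empty_mask_yields_no_records(self, caplog):
        rng = np.random.default_rng(1)
        labels = np.zeros((10, 10), dtype=int)
        stack = _toy_stack(labels, rng)
        with caplog.at_level(logging.WARNING, logger="celloc.coloc"):
            records = coloc.measure_dataset([stack], [LabelMask(labels=labels)])
        assert records == []
        assert "empty mask" in caplog.text

    def test_constant_cell_dropped_and_logged(self, caplog):
        rng = np.random.default_rng(2)
        labels = np.zeros((10, 10), dtype=int)
        labels[1:4, 1:4] = 1
        labels[6:9, 6:9] = 2
        stack = _toy_stack(labels, rng)
        stack.channels["comarker"][labels == 2] = 5.0  # constant in cell 2
        with caplog.at_level(logging.WARNING, logger="celloc.coloc"):
            records = coloc.measure_dataset([stack], [LabelMask(labels=labels)])
        assert [r.cell_label for r in records] == [1]
        assert "dropped" in caplog.text

    def test_mask_count_mismatch_rejected(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((10, 10), dtype=int)
        with pytest.raises(ValueError):
            coloc.measure_dataset([_toy_stack(labels, rng)], [])

    def test_pure_membrane_dataset_has_unit_correlations(self):
        spec = SceneSpec(alpha=1.0, alpha_jitter_sd=0.0, psf_sigma=0.0,
                         noise_model=NoiseModel(0.0, 0.0), n_cells=3,
                         genotype_label="WT")
        stacks, masks = [], []
        for _, stack, truth in synthgen.generate_dataset([spec], 2,
                                                         base_seed=9):
            stacks.append(stack)
            masks.append(truth_label_mask(truth))
        records = coloc.measure_dataset(stacks, masks)
        assert len(records) == 6
        assert all(r.pearson_r == pytest.approx(1.0, abs=1e-12)
                   for r in records)


class TestRandomizationPvalue:
    def _structured(self, seed=0, size=40):
        rng = np.random.default_rng(seed)
        labels = np.zeros((size, size), dtype=int)
        labels[4:-4, 4:-4] = 1
        yy, xx = np.mgrid[:size, :size]
        a = np.sin(yy / 4.0) + np.cos(xx / 5.0) + rng.normal(0, 0.05, (size, size))
        return a, labels, rng

    def test_perfect_correlation_hits_smoothing_floor(self):
        a, labels, _ = self._structured()
        p = coloc.randomization_pvalue(a, a.copy(), LabelMask(labels), 1,
                                       n_shuffles=99, block=8, seed=1)
        assert p == pytest.approx(1.0 / 100.0)

    def test_zero_shuffles_rejected(self):
        a, labels, _ = self._structured()
        with pytest.raises(ValueError):
            coloc.randomization_pvalue(a, a, LabelMask(labels), 1,
                                       n_shuffles=0)

    def test_oversized_block_rejected(self):
        a, labels, _ = self._structured()
        with pytest.raises(ValueError, match="block"):
            coloc.randomization_pvalue(a, a, LabelMask(labels), 1,
                                       n_shuffles=5, block=64)

    def test_null_calibration(self):
        """With an independent-noise comarker the p-value is uniform: over
        200 null ROIs the rejection rate at 0.05 stays inside the binomial
        95% interval around 0.05."""
        hits = 0
        n_rois = 200
        rng = np.random.default_rng(77)
        labels = np.zeros((24, 24), dtype=int)
        labels[2:-2, 2:-2] = 1
        mask = LabelMask(labels)
        for i in range(n_rois):
            a = rng.normal(0, 1, (24, 24))
            b = rng.normal(0, 1, (24, 24))
            p = coloc.randomization_pvalue(a, b, mask, 1, n_shuffles=99,
                                           block=4, seed=1000 + i)
            hits += p <= 0.05
        half_width = 1.96 * np.sqrt(0.05 * 0.95 / n_rois)
        assert abs(hits / n_rois - 0.05) <= half_width
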