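import numpy as np
import pytest

from hcscreen.imaging import (
    aggregate_well,
    cytoplasmic_masks,
    process_field,
    quantify_cells,
    segment_nuclei,
)
from hcscreen.synthetic_data import FieldImageSpec, render_field


def disk_label(shape, center, radius, label=1):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    out = np.zeros(shape, dtype=np.int32)
    out[d2 <= radius**2] = label
    return out


def brute_force_ring(labels, target_label, ring_width):
    """Independent oracle: pixels whose min distance to any pixel of the
    target nucleus lies in (0, ring_width], excluding all nuclear pixels."""
    own = np.argwhere(labels == target_label)
    ring = np.zeros(labels.shape, dtype=bool)
    for r in range(labels.shape[0]):
        for c in range(labels.shape[1]):
            if labels[r, c] != 0:
                continue
            d = np.sqrt(((own - (r, c)) ** 2).sum(axis=1)).min()
            if 0 < d <= ring_width:
                ring[r, c] = True
    return ring


class TestSegmentNuclei:
    def test_blank_image_gives_zero_nuclei(self):
        assert segment_nuclei(np.full((64, 64), 100.0)).max() == 0

    def test_planted_disks_recovered_exactly(self):
        img = render_field(FieldImageSpec(n_cells=50, noise_sd=10.0, seed=1))
        labels = segment_nuclei(img.dna, min_area=20)
        assert labels.max() == 50
        assert np.array_equal(np.unique(labels)[1:], np.arange(1, 51))

    def test_min_area_filter(self):
        image = np.full((64, 64), 100.0)
        image[30:32, 30:32] = 5000.0  # area 4 object
        assert segment_nuclei(image, smoothing_sigma=0, min_area=10).max() == 0
        assert segment_nuclei(image, smoothing_sigma=0, min_area=2).max() == 1

    def test_border_nucleus_excluded_by_default(self):
        image = np.full((64, 64), 100.0)
        image[0:6, 20:26] = 5000.0
        assert segment_nuclei(image, min_area=4).max() == 0
        assert segment_nuclei(image, min_area=4, border_policy="include").max() == 1

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_nuclei(np.zeros((0, 0)))

    def test_count_recovery_over_seeds(self):
        for seed in range(10):
            img = render_field(FieldImageSpec(n_cells=30, noise_sd=10.0, seed=seed))
            assert segment_nuclei(img.dna, min_area=20).max() == 30


class TestCytoplasmicMasks:
    def test_zero_ring_width_empty(self):
        labels = disk_label((32, 32), (16, 16), 5)
        assert cytoplasmic_masks(labels, 0).max() == 0

    def test_negative_ring_width_rejected(self):
        with pytest.raises(ValueError):
            cytoplasmic_masks(disk_label((32, 32), (16, 16), 5), -1)

    @pytest.mark.parametrize("radius,width", [(5, 5), (4, 3), (6, 4)])
    def test_single_nucleus_matches_brute_force(self, radius, width):
        labels = disk_label((48, 48), (24, 24), radius)
        ring = cytoplasmic_masks(labels, width) == 1
        oracle = brute_force_ring(labels, 1, width)
        assert np.array_equal(ring, oracle)
        # the Euclidean dilation ring sits inside the ideal annulus r..r+w
        yy, xx = np.ogrid[:48, :48]
        d2 = (yy - 24) ** 2 + (xx - 24) ** 2
        annulus = (d2 > radius**2) & (d2 <= (radius + width) ** 2)
        assert not np.any(ring & ~annulus)
        assert ring.sum() >= 0.9 * annulus.sum()

    def test_two_close_nuclei_masks_disjoint(self):
        labels = disk_label((64, 64), (30, 28), 4) + disk_label((64, 64), (30, 41), 4, label=2)
        rings = cytoplasmic_masks(labels, 5)
        assert set(np.unique(rings)) == {0, 1, 2}
        # disjoint by construction of a label image; also excludes all nuclei
        assert not np.any((rings > 0) & (labels > 0))
        # contested pixels went to the nearer center: the midline column
        mid_col = (28 + 41) // 2
        left = np.argwhere(rings == 1)[:, 1]
        right = np.argwhere(rings == 2)[:, 1]
        assert left.max() <= mid_col + 1 and right.min() >= mid_col

    def test_mask_disjointness_area_sum(self, noisy_field):
        labels = segment_nuclei_for(noisy_field)
        rings = cytoplasmic_masks(labels, 5)
        per_label = [(rings == lab).sum() for lab in range(1, rings.max() + 1)]
        assert sum(per_label) == (rings > 0).sum()


def segment_nuclei_for(img):
    return segment_nuclei(img.dna, min_area=20)


class TestQuantifyCells:
    def test_uniform_gfp(self):
        labels = disk_label((32, 32), (16, 16), 5)
        rings = cytoplasmic_masks(labels, 4)
        records = quantify_cells(np.full((32, 32), 7.5), rings, labels)
        assert len(records) == 1
        assert records[0].mean_gfp == 7.5
        assert records[0].nuclear_area == int((labels == 1).sum())

    def test_noiseless_phantom_exact(self, noiseless_field):
        records = process_field(
            noiseless_field.dna, noiseless_field.gfp, min_area=20, ring_width_px=5
        )
        assert len(records) == 50
        assert all(r.mean_gfp == 300.0 for r in records)

    def test_noisy_phantom_within_one_percent(self, noisy_field):
        records = process_field(noisy_field.dna, noisy_field.gfp, min_area=20, ring_width_px=5)
        assert len(records) == 50
        for r in records:
            assert r.mean_gfp == pytest.approx(300.0, rel=0.01)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantify_cells(np.zeros((8, 8)), np.zeros((9, 9), dtype=int))

    @pytest.mark.parametrize("scale", [0.5, 2.0, 7.25])
    def test_intensity_linearity(self, noisy_field, scale):
        labels = segment_nuclei(noisy_field.dna, min_area=20)
        rings = cytoplasmic_masks(labels, 5)
        base = quantify_cells(noisy_field.gfp, rings, labels)
        scaled = quantify_cells(noisy_field.gfp.astype(float) * scale, rings, labels)
        for b, s in zip(base, scaled):
            assert s.mean_gfp == pytest.approx(scale * b.mean_gfp, rel=1e-12)


class TestAggregateWell:
    def make_cell(self, gfp):
        from hcscreen.imaging import CellRecord

        return CellRecord(label=1, centroid=(0, 0), nuclear_area=10, cytoplasm_area=20, mean_gfp=gfp)

    def test_twelve_uniform_fields(self):
        fields = [[self.make_cell(5.0)] * 10 for _ in range(12)]
        m = aggregate_well(fields, plate_id="P", well="A2")
        assert m.cell_count == 120
        assert m.avg_gfp == 5.0
        assert m.n_fields == 12

    def test_empty_fields_missing_gfp(self):
        m = aggregate_well([[], [], []])
        assert m.cell_count == 0 and m.avg_gfp is None

    def test_unweighted_mean_across_fields(self):
        fields = [[self.make_cell(10.0)] * 2, [self.make_cell(20.0)] * 3]
        m = aggregate_well(fields)
        assert m.cell_count == 5
        assert m.avg_gfp == pytest.approx(16.0)  # (2*10 + 3*20)/5

    def test_zero_fields_rejected(self):
        with pytest.raises(ValueError):
            aggregate_well([])
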