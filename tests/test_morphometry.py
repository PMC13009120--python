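from collections import deque
from itertools import product

import numpy as np
import pytest

from snapia.morphometry import (
    bridges_both_thalami,
    chord_through_centroid,
    label_components,
    largest_area_slice,
    measure_thalamus,
    slice_chord,
    slices_with_signal,
)
from snapia.volume_io import BinaryMask, VoxelGrid

from conftest import make_mask


def flood_fill_components(data: np.ndarray, connectivity: int) -> list[set]:
    """Independent BFS oracle for connected components."""
    offsets = [
        off
        for off in product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0)
        and {6: sum(abs(o) for o in off) == 1, 18: sum(abs(o) for o in off) <= 2, 26: True}[connectivity]
    ]
    seen = np.zeros(data.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(data)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for off in offsets:
                w = tuple(a + b for a, b in zip(v, off))
                if all(0 <= c < s for c, s in zip(w, data.shape)) and data[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


class TestLabelComponents:
    def test_two_disjoint_cubes(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:3, 1:3, 1:3] = True  # 8 voxels
        data[6:9, 6:9, 6:9] = True  # 27 voxels
        comps = label_components(make_mask(data))
        assert comps.n == 2
        assert list(comps.sizes) == [27, 8]  # ordered by decreasing size
        assert comps.labels[7, 7, 7] == 1 and comps.labels[1, 1, 1] == 2

    def test_empty_mask(self):
        comps = label_components(make_mask(np.zeros((4, 4, 4))))
        assert comps.n == 0 and not comps.labels.any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_flood_fill_oracle_on_random_grids(self, connectivity, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(10, 21, size=3))
        data = rng.random(shape) < 0.25
        comps = label_components(make_mask(data), connectivity)
        oracle = flood_fill_components(data, connectivity)
        assert comps.n == len(oracle)
        assert sorted(comps.sizes, reverse=True) == sorted((len(c) for c in oracle), reverse=True)
        # same partition: every oracle component maps to exactly one label
        for comp in oracle:
            labels = {int(comps.labels[v]) for v in comp}
            assert len(labels) == 1 and labels != {0}
        assert comps.sizes.sum() == data.sum()


class TestChord:
    def test_axis_aligned_rectangle(self):
        rect = np.zeros((20, 20), dtype=bool)
        rect[5:15, 9:11] = True  # 10 x 2 voxels at 1 mm
        assert chord_through_centroid(rect, 0, (1, 1)).length_mm == pytest.approx(10.0)
        assert chord_through_centroid(rect, 1, (1, 1)).length_mm == pytest.approx(2.0)

    def test_empty_slice_is_zero(self):
        assert chord_through_centroid(np.zeros((5, 5), dtype=bool), 0, (1, 1)).length_mm == 0.0

    @pytest.mark.parametrize("angle_deg", [10, 30, 45, 60, 120])
    def test_rotated_rectangle_recovers_true_length(self, angle_deg):
        """Principal-axis chord of a rotated 10x2 mm rectangle stays within a
        voxel diagonal of the analytic 10 mm length."""
        theta = np.deg2rad(angle_deg)
        n = 40
        ii, jj = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
        u = ii * np.cos(theta) + jj * np.sin(theta)
        v = -ii * np.sin(theta) + jj * np.cos(theta)
        rect = (np.abs(u) <= 5.0) & (np.abs(v) <= 1.0)
        length = chord_through_centroid(rect, 0 if angle_deg <= 45 else 1, (1, 1)).length_mm
        assert length == pytest.approx(10.0, abs=np.sqrt(2.0))

    @pytest.mark.parametrize("angle_deg", [0, 20, 50, 75])
    def test_rotation_robust_on_analytic_ellipse(self, angle_deg):
        theta = np.deg2rad(angle_deg)
        n = 60
        ii, jj = np.meshgrid(np.arange(n) - n / 2, np.arange(n) - n / 2, indexing="ij")
        u = ii * np.cos(theta) + jj * np.sin(theta)
        v = -ii * np.sin(theta) + jj * np.cos(theta)
        ellipse = (u / 12.0) ** 2 + (v / 5.0) ** 2 <= 1.0
        major_axis = 0 if angle_deg <= 45 else 1
        major = chord_through_centroid(ellipse, major_axis, (1, 1)).length_mm
        minor = chord_through_centroid(ellipse, 1 - major_axis, (1, 1)).length_mm
        assert major == pytest.approx(24.0, abs=np.sqrt(2.0))
        assert minor == pytest.approx(10.0, abs=np.sqrt(2.0))


def _ellipsoid_mask(shape, center, semi, spacing=(1.0, 1.0, 1.0)):
    grids = np.meshgrid(*(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij")
    m = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi)) <= 1.0
    return make_mask(m, spacing)


class TestMeasureThalamus:
    def test_analytic_ellipsoid_dimensions(self):
        # semi-axes (10, 15, 12) mm -> A-P length 30, S-I height 24
        thal = _ellipsoid_mask((40, 50, 40), (20, 25, 20), (10, 15, 12))
        meas = measure_thalamus(thal)
        assert meas.length_axial_mm == pytest.approx(30.0, abs=1.0)
        assert meas.height_coronal_mm == pytest.approx(24.0, abs=1.0)
        assert meas.chosen_axial_slice == 20 and meas.chosen_coronal_slice == 25

    def test_single_voxel_mask_measures_one_spacing(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        meas = measure_thalamus(make_mask(data, (0.7, 0.7, 0.7)))
        assert meas.length_axial_mm == pytest.approx(0.7)
        assert meas.height_coronal_mm == pytest.approx(0.7)

    def test_translation_invariance(self):
        base = _ellipsoid_mask((40, 50, 40), (14, 20, 16), (6, 9, 7))
        shifted = make_mask(np.roll(base.data, (4, 5, 3), axis=(0, 1, 2)))
        a, b = measure_thalamus(base), measure_thalamus(shifted)
        assert a.length_axial_mm == pytest.approx(b.length_axial_mm)
        assert a.height_coronal_mm == pytest.approx(b.height_coronal_mm)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            measure_thalamus(make_mask(np.zeros((4, 4, 4))))

    def test_phantom_thalamus_matches_generator_truth(self, phantoms):
        truth = phantoms["simple"]
        ax, ay, az = truth.spec.thalamus_semi_axes
        meas = measure_thalamus(truth.thal_left)
        assert meas.length_axial_mm == pytest.approx(2 * ay, abs=1.0)
        assert meas.height_coronal_mm == pytest.approx(2 * az, abs=1.0)


class TestBridging:
    def _scene(self, gap_vox):
        shape = (30, 9, 9)
        left = np.zeros(shape, dtype=bool)
        right = np.zeros(shape, dtype=bool)
        left[:10] = True
        right[20:] = True
        comp = np.zeros(shape, dtype=bool)
        comp[10 : 20 - gap_vox, 4, 4] = True  # ends gap_vox voxels short of right
        return make_mask(comp), make_mask(left), make_mask(right)

    def test_spanning_cylinder_bridges(self):
        comp, left, right = self._scene(0)
        assert bridges_both_thalami(comp, left, right)

    def test_one_sided_blob_does_not_bridge(self):
        comp, left, right = self._scene(5)
        assert not bridges_both_thalami(comp, left, right)

    def test_one_voxel_short_needs_one_voxel_gap(self):
        comp, left, right = self._scene(1)
        assert bridges_both_thalami(comp, left, right, max_gap_mm=1.0)
        assert not bridges_both_thalami(comp, left, right, max_gap_mm=0.0)


class TestSlicesWithSignal:
    def test_empty_and_segment(self):
        assert slices_with_signal(make_mask(np.zeros((5, 5, 5))), "sagittal") == []
        data = np.zeros((10, 5, 5), dtype=bool)
        data[3:7, 2, 2] = True  # 4-voxel L-R segment
        assert slices_with_signal(make_mask(data), "sagittal") == [3, 4, 5, 6]

    def test_phantom_filiform_spans_its_gap(self, phantoms):
        truth = phantoms["filiform"]
        n = len(slices_with_signal(truth.ia_mask, "sagittal"))
        assert n == pytest.approx(truth.true_lr_length_mm, abs=1)

    def test_largest_area_slice_tie_breaks_low(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[1, :2, :2] = True
        data[3, :2, :2] = True
        assert largest_area_slice(make_mask(data), "sagittal") == 1
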