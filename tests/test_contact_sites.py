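"""Contact-site calls, region partitioning and the EM distance rule."""

import math

import numpy as np
import pytest

from conftest import make_stack8, spot_image
from oracles import nearest_mask_pixel_oracle
from vesicoloc.errors import ContractError, GeometryError
from vesicoloc.contact_sites import (
    EMAnnotation,
    MMCSConfig,
    count_contacts_by_region,
    detect_mmcs,
    em_direct_contacts,
    nearest_structure_direction,
    partition_cell_regions,
)


class TestNearestStructureDirection:
    def test_single_pixel_due_east(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10, 25] = True
        (dx, dy), dist = nearest_structure_direction((5.0, 10.0), mask)
        assert (dx, dy) == (1.0, 0.0)
        assert dist == 20.0

    def test_point_inside_mask_has_zero_distance(self):
        mask = np.zeros((32, 32), dtype=bool)
        mask[10:20, 10:20] = True
        (dx, dy), dist = nearest_structure_direction((15.0, 15.0), mask)
        assert dist == 0.0
        assert math.hypot(dx, dy) == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(GeometryError):
            nearest_structure_direction((5.0, 5.0), np.zeros((8, 8), dtype=bool))

    def test_matches_exhaustive_search_on_sparse_masks(self, rng):
        for _ in range(20):
            mask = rng.random((24, 24)) < 0.05
            if not mask.any():
                continue
            point = (rng.uniform(0, 23), rng.uniform(0, 23))
            ix, iy = int(round(point[0])), int(round(point[1]))
            if mask[iy, ix]:
                continue
            (dx, dy), dist = nearest_structure_direction(point, mask)
            oy, ox, od = nearest_mask_pixel_oracle(point, mask)
            assert dist == pytest.approx(od)
            assert point[0] + dx * dist == pytest.approx(ox)
            assert point[1] + dy * dist == pytest.approx(oy)


class TestDetectMMCS:
    def _stack_with(self, vesicle_img, mito_img):
        return make_stack8({"vesicle": vesicle_img, "mitochondria": mito_img})

    def test_flat_mito_channel_yields_no_contacts(self):
        vesicle = spot_image((128, 128), [(64, 64)], 3.5, 200.0)
        mito_mask = np.zeros((128, 128), dtype=bool)
        mito_mask[:, 100] = True
        stack = self._stack_with(vesicle.astype(np.uint8), np.zeros((128, 128)))
        sites = detect_mmcs([(64.0, 64.0)], stack, "vesicle", "mitochondria",
                            mito_mask, MMCSConfig(background_mode="cutoff"))
        assert not sites[0].is_contact

    def test_touching_vesicle_is_contact_and_isolated_is_not(self):
        mito = np.zeros((160, 160))
        mito[:, 80:82] = 200.0  # bright vertical filament at x=80-81
        mito_mask = mito > 0
        vesicle = spot_image((160, 160), [(77, 80), (20, 80)], 3.5, 200.0)
        stack = self._stack_with(vesicle, mito)
        sites = detect_mmcs(
            [(77.0, 80.0), (20.0, 80.0)], stack, "vesicle", "mitochondria",
            mito_mask, MMCSConfig(background_mode="cutoff"),
        )
        assert sites[0].is_contact  # 3 px from the filament
        assert not sites[1].is_contact  # 60 px away

    def test_disjoint_signal_ranges_are_not_a_contact(self):
        mito = np.zeros((160, 160))
        mito[:, 79:82] = 200.0
        mito_mask = mito > 0
        # vesicle 15 px from the filament: both channels signal on the
        # 50-px line but on disjoint sample ranges
        vesicle = spot_image((160, 160), [(65, 80)], 3.5, 200.0)
        stack = self._stack_with(vesicle, mito)
        sites = detect_mmcs([(65.0, 80.0)], stack, "vesicle", "mitochondria",
                            mito_mask, MMCSConfig(background_mode="cutoff"))
        (site,) = sites
        assert not site.is_contact
        assert site.line is not None

    def test_synthetic_truth_recovery(self):
        from vesicoloc.imaging_io import display_ranges_from_stack, to_8bit
        from vesicoloc.synthetic_scene import SceneParams, generate_scene

        tp = fn = fp = tn = 0
        for seed in range(2):
            params = SceneParams(seed=seed, contact_fraction=0.4)
            scene, stack = generate_scene(params)
            stack8 = to_8bit(stack, display_ranges_from_stack(stack))
            sites = detect_mmcs(
                [(v.x, v.y) for v in scene.vesicles], stack8, "vesicle",
                "mitochondria", scene.mito_mask,
            )
            for v, s in zip(scene.vesicles, sites):
                tp += v.is_contacting and s.is_contact
                fn += v.is_contacting and not s.is_contact
                fp += (not v.is_contacting) and s.is_contact
                tn += (not v.is_contacting) and not s.is_contact
        assert tp / (tp + fn) >= 0.9
        assert fp / (fp + tn) <= 0.1


class TestPartitionCellRegions:
    @staticmethod
    def _disk(shape, center, radius):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return (xx - center[0]) ** 2 + (yy - center[1]) ** 2 <= radius**2

    def test_circular_nucleus_gives_double_diameter_disk(self):
        cell = np.ones((200, 200), dtype=bool)
        nucleus = self._disk((200, 200), (100, 100), 10.0)
        part = partition_cell_regions(nucleus, cell)
        assert part.nuclear_diameter_px == pytest.approx(20.0, rel=0.03)
        # perinuclear disk radius equals the nuclear diameter
        assert part.region_of(100 + 19, 100) == "perinuclear"
        assert part.region_of(100 + 21, 100) == "peripheral"

    def test_elliptical_nucleus_uses_equivalent_area_diameter(self):
        cell = np.ones((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        nucleus = ((xx - 100) / 15.0) ** 2 + ((yy - 100) / 6.0) ** 2 <= 1.0
        part = partition_cell_regions(nucleus, cell)
        # 30 x 12 px axes: equivalent diameter 2*sqrt(15*6) ~= 18.97
        assert part.nuclear_diameter_px == pytest.approx(18.97, rel=0.03)

    def test_masks_partition_the_cell_exactly(self):
        cell = self._disk((160, 160), (80, 80), 70.0)
        nucleus = self._disk((160, 160), (70, 85), 15.0)
        part = partition_cell_regions(nucleus, cell)
        np.testing.assert_array_equal(
            part.perinuclear_mask | part.peripheral_mask, cell
        )
        assert not (part.perinuclear_mask & part.peripheral_mask).any()

    def test_empty_masks_rejected(self):
        with pytest.raises(GeometryError):
            partition_cell_regions(np.zeros((8, 8), dtype=bool),
                                   np.ones((8, 8), dtype=bool))


class TestCountContactsByRegion:
    @staticmethod
    def _partition():
        cell = np.ones((200, 200), dtype=bool)
        yy, xx = np.mgrid[0:200, 0:200]
        nucleus = (xx - 100) ** 2 + (yy - 100) ** 2 <= 20**2
        return partition_cell_regions(nucleus, cell)

    def test_no_contacts(self):
        counts = count_contacts_by_region([], self._partition())
        assert counts == {"perinuclear": 0, "peripheral": 0, "whole_cell": 0}

    def test_whole_cell_is_sum_of_regions(self):
        from vesicoloc.contact_sites import ContactSite

        part = self._partition()
        sites = [
            ContactSite(0, (105.0, 100.0), True),   # perinuclear
            ContactSite(1, (110.0, 95.0), True),    # perinuclear
            ContactSite(2, (120.0, 108.0), True),   # perinuclear
            ContactSite(3, (190.0, 10.0), True),    # peripheral
            ContactSite(4, (5.0, 190.0), True),     # peripheral
            ContactSite(5, (100.0, 100.0), False),  # not a contact
        ]
        counts = count_contacts_by_region(sites, part)
        assert counts == {"perinuclear": 3, "peripheral": 2, "whole_cell": 5}

    def test_region_assignment_matches_truth_away_from_boundary(self):
        from vesicoloc.synthetic_scene import SceneParams, sample_scene, scene_truth_table

        params = SceneParams(seed=13)
        scene = sample_scene(params)
        table = scene_truth_table(scene)
        part = partition_cell_regions(scene.nucleus_mask, scene.cell_mask)
        cx, cy = part.nuclear_center
        for _, row in table.iterrows():
            margin = abs(math.hypot(row.x - cx, row.y - cy) - part.nuclear_diameter_px)
            if margin > 1.0:
                assert part.region_of(row.x, row.y) == row.region


class TestEMDirectContacts:
    def test_hand_computed_rule(self):
        # mean MVE radius = 0.3 um; contact iff gap < 0.3
        annotations = [
            EMAnnotation("MVE", (0.0, 0.0), 0.2),
            EMAnnotation("MVE", (10.0, 0.0), 0.4),
            EMAnnotation("mitochondrion", (0.65, 0.0), 0.2),  # gap 0.25 to MVE0
            EMAnnotation("mitochondrion", (0.95, 0.0), 0.2),  # gap 0.55 to MVE0
        ]
        pairs, count = em_direct_contacts(annotations)
        assert count == 1
        assert pairs[0][:2] == (0, 2)
        assert pairs[0][2] == pytest.approx(0.25)

    def test_gap_just_above_mean_radius_is_not_contact(self):
        annotations = [
            EMAnnotation("MVE", (0.0, 0.0), 0.2),
            EMAnnotation("MVE", (10.0, 0.0), 0.4),
            EMAnnotation("mitochondrion", (0.75, 0.0), 0.2),  # gap 0.35
        ]
        _, count = em_direct_contacts(annotations)
        assert count == 0

    def test_overlapping_boundaries_always_contact(self):
        annotations = [
            EMAnnotation("MVE", (0.0, 0.0), 0.3),
            EMAnnotation("mitochondrion", (0.4, 0.0), 0.2),  # gap -0.1
        ]
        pairs, count = em_direct_contacts(annotations)
        assert count == 1 and pairs[0][2] < 0

    def test_no_mves_rejected(self):
        with pytest.raises(ContractError):
            em_direct_contacts([EMAnnotation("mitochondrion", (0, 0), 1.0)])

    def test_adding_larger_mve_never_removes_contacts(self):
        base = [
            EMAnnotation("MVE", (0.0, 0.0), 0.25),
            EMAnnotation("mitochondrion", (0.6, 0.0), 0.2),
            EMAnnotation("mitochondrion", (3.0, 0.0), 0.2),
        ]
        pairs_before, _ = em_direct_contacts(base)
        enlarged = base + [EMAnnotation("MVE", (50.0, 50.0), 1.5)]
        pairs_after, _ = em_direct_contacts(enlarged)
        before = {p[:2] for p in pairs_before}
        after = {p[:2] for p in pairs_after}
        assert before <= after

    def test_csv_round_trip(self, tmp_path):
        from vesicoloc.contact_sites import read_em_annotations, write_em_annotations

        annotations = [
            EMAnnotation("MVE", (1.5, 2.5), 0.3, ilv_count=12),
            EMAnnotation("mitochondrion", (4.0, 1.0), 0.6),
        ]
        path = tmp_path / "em.csv"
        write_em_annotations(annotations, path)
        back = read_em_annotations(path)
        assert back == annotations
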