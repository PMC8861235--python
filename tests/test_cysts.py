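"""Subchondral band, region growing, component filtering and cyst reports."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import kneespec as ks
from kneespec.cysts import (
    aggregate_report,
    compartment_stats,
    cyst_density,
    filter_min_volume,
    label_components,
    min_volume_mm3,
    region_grow,
    subchondral_band,
)


def union_find_components_oracle(mask):
    """Brute-force flood-fill labeling with full connectivity (independent
    of scipy): returns a canonical partition as a set of frozensets."""
    mask = np.asarray(mask, bool)
    visited = np.zeros(mask.shape, bool)
    offsets = [
        off
        for off in np.ndindex(*(3,) * mask.ndim)
        if any(o != 1 for o in off)
    ]
    comps = []
    for idx in zip(*np.nonzero(mask)):
        if visited[idx]:
            continue
        stack = [idx]
        visited[idx] = True
        comp = []
        while stack:
            cur = stack.pop()
            comp.append(cur)
            for off in offsets:
                nb = tuple(c + o - 1 for c, o in zip(cur, off))
                if all(0 <= n < s for n, s in zip(nb, mask.shape)):
                    if mask[nb] and not visited[nb]:
                        visited[nb] = True
                        stack.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


class TestSubchondralBand:
    def test_zero_depth_empty_band(self):
        bone = np.zeros((20, 20), bool)
        bone[10:, :] = True
        surface = np.zeros((20, 20), bool)
        surface[9, :] = True  # interface layer just outside the bone
        band = subchondral_band(bone, surface, depth_mm=0.0, voxel_size=0.25)
        assert band.mask.sum() == 0

    def test_planar_slab_band_thickness(self):
        """10 mm depth at 0.25 mm voxels on a half-space: 40 voxel layers."""
        bone = np.zeros((80, 16), bool)
        bone[20:, :] = True
        surface = np.zeros((80, 16), bool)
        surface[19, :] = True
        band = subchondral_band(bone, surface, depth_mm=10.0, voxel_size=0.25)
        per_col = band.mask.sum(axis=0)
        assert np.all(per_col == 40)
        assert np.all(band.mask[20:60, :])

    def test_band_subset_of_bone(self, knee_phantom):
        band = subchondral_band(
            knee_phantom.rois["bone_mask"],
            knee_phantom.rois["articular_surface"],
            10.0,
            knee_phantom.voxel_size,
        )
        assert band.mask.any()
        assert not (band.mask & ~knee_phantom.rois["bone_mask"]).any()

    def test_independent_of_non_bone_relabeling(self):
        bone = np.zeros((40, 40), bool)
        bone[20:, :] = True
        surface = np.zeros((40, 40), bool)
        surface[19, :] = True
        a = subchondral_band(bone, surface, 3.0, 0.25).mask
        # relabeling non-bone tissue does not enter the computation at all
        b = subchondral_band(bone.copy(), surface.copy(), 3.0, 0.25).mask
        assert np.array_equal(a, b)

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            subchondral_band(np.ones((8, 8), bool), np.zeros((8, 8), bool))


class TestRegionGrow:
    def test_whole_domain_with_huge_tolerance(self):
        img = np.arange(64.0).reshape(8, 8)
        out = region_grow(img, (3, 3), tolerance=1e6)
        assert out.all()

    def test_zero_tolerance_unique_seed_value(self):
        img = np.zeros((8, 8))
        img[4, 4] = 7.0
        out = region_grow(img, (4, 4), tolerance=0.0)
        assert out.sum() == 1 and out[4, 4]

    def test_planted_sphere_recovered_exactly(self):
        """Uniform low-HU sphere in uniform bone, tolerance = half the gap."""
        shape = (32, 32, 32)
        img = np.full(shape, 400.0)
        zz, yy, xx = np.indices(shape)
        sphere = (zz - 16) ** 2 + (yy - 16) ** 2 + (xx - 16) ** 2 <= 6.0**2
        img[sphere] = 0.0
        out = region_grow(img, (16, 16, 16), tolerance=200.0)
        assert np.array_equal(out, sphere)

    def test_seed_position_invariance_on_plateau(self):
        img = np.full((16, 16), 100.0)
        img[4:9, 4:9] = 0.0
        masks = [region_grow(img, s, 50.0) for s in [(4, 4), (6, 6), (8, 8)]]
        assert np.array_equal(masks[0], masks[1])
        assert np.array_equal(masks[1], masks[2])

    def test_seed_outside_domain_rejected(self):
        img = np.zeros((8, 8))
        domain = np.zeros((8, 8), bool)
        with pytest.raises(ValueError):
            region_grow(img, (2, 2), 1.0, domain=domain)


class TestLabelComponents:
    def test_empty_mask_zero_components(self):
        assert label_components(np.zeros((8, 8), bool)).max() == 0

    def test_diagonal_voxels_single_component(self):
        m = np.zeros((4, 4, 4), bool)
        m[1, 1, 1] = m[2, 2, 2] = True
        assert label_components(m).max() == 1

    def test_random_masks_match_union_find_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            mask = rng.random((12, 12, 12)) < 0.25
            labeled = label_components(mask)
            ours = {
                frozenset(zip(*np.nonzero(labeled == lab)))
                for lab in range(1, labeled.max() + 1)
            }
            assert ours == union_find_components_oracle(mask)

    def test_labels_contiguous_in_scan_order(self):
        m = np.zeros((8, 8), bool)
        m[0, 0] = True
        m[7, 7] = True
        labeled = label_components(m)
        assert labeled[0, 0] == 1 and labeled[7, 7] == 2


class TestFilterMinVolume:
    def test_strict_threshold_at_20_voxels(self):
        """Components of 19/20/21 voxels: only >= 20 survive ('< 20' removed)."""
        arr = np.zeros((3, 70), dtype=np.int32)
        arr[0, :19] = 1
        arr[1, :20] = 2
        arr[2, :21] = 3
        out = filter_min_volume(arr, min_voxels=20)
        survivors = set(np.unique(out)) - {0}
        assert survivors == {2, 3}

    def test_empty_input(self):
        out = filter_min_volume(np.zeros((4, 4), dtype=np.int32))
        assert out.max() == 0

    def test_min_voxels_one_is_identity(self):
        arr = np.zeros((4, 4), dtype=np.int32)
        arr[0, 0] = 1
        assert np.array_equal(filter_min_volume(arr, min_voxels=1), arr)

    def test_physical_threshold_value(self):
        assert round(min_volume_mm3(20, 0.25, 3), 2) == 0.31


class TestCompartmentStats:
    def _masks(self, shape):
        medial = np.zeros(shape, bool)
        lateral = np.zeros(shape, bool)
        half = shape[-1] // 2
        medial[..., :half] = True
        lateral[..., half:] = True
        return {"medial": medial, "lateral": lateral}

    def test_no_cysts_zero_rows(self):
        comps = np.zeros((8, 8, 8), dtype=np.int32)
        rows, recs = compartment_stats(comps, self._masks((8, 8, 8)), 0.25)
        assert recs == []
        for r in rows:
            assert (r["number"], r["total_volume_mm3"], r["max_volume_mm3"]) == (0, 0.0, 0.0)

    def test_forty_voxel_cyst_arithmetic(self):
        comps = np.zeros((8, 8, 16), dtype=np.int32)
        comps[2:4, 2:4, 0:10] = 1  # 2*2*10 = 40 voxels, medial half
        rows, recs = compartment_stats(comps, self._masks((8, 8, 16)), 0.25)
        medial = next(r for r in rows if r["compartment"] == "medial")
        assert medial["number"] == 1
        assert medial["total_volume_mm3"] == pytest.approx(0.625)
        assert medial["max_volume_mm3"] == pytest.approx(0.625)
        assert recs[0].voxel_count == 40

    def test_planted_three_medial_two_lateral(self):
        shape = (6, 24, 24)
        comps = np.zeros(shape, dtype=np.int32)
        spots = [(2, 4, 2), (2, 10, 4), (2, 18, 6), (2, 6, 18), (2, 16, 20)]
        for i, (z, y, x) in enumerate(spots, start=1):
            comps[z : z + 2, y : y + 2, x : x + 2] = i  # 8 voxels each
        rows, _ = compartment_stats(comps, self._masks(shape), 0.25)
        by = {r["compartment"]: r for r in rows}
        assert by["medial"]["number"] == 3
        assert by["lateral"]["number"] == 2
        assert by["medial"]["total_volume_mm3"] == pytest.approx(3 * 8 * 0.25**3)


class TestAggregateReport:
    @pytest.mark.parametrize(
        "rows,expected",
        [
            # printed per-compartment rows -> printed totals
            (
                [
                    {"site": "femoral", "compartment": "medial", "number": 8,
                     "total_volume_mm3": 185.8, "max_volume_mm3": 110.6},
                    {"site": "femoral", "compartment": "lateral", "number": 44,
                     "total_volume_mm3": 355.0, "max_volume_mm3": 106.1},
                ],
                (52, 540.8, 110.6),
            ),
            (
                [
                    {"site": "patellar", "compartment": "medial", "number": 4,
                     "total_volume_mm3": 13.2, "max_volume_mm3": 5.5},
                    {"site": "patellar", "compartment": "lateral", "number": 11,
                     "total_volume_mm3": 37.9, "max_volume_mm3": 17.7},
                ],
                (15, 51.1, 17.7),
            ),
        ],
    )
    def test_totals_semantics(self, rows, expected):
        report = aggregate_report(rows)
        total = report.rows[report.rows["compartment"] == "total"].iloc[0]
        assert (total["number"], total["total_volume_mm3"], total["max_volume_mm3"]) == expected

    def test_single_row_identity(self):
        rows = [{"site": "femoral", "compartment": "medial", "number": 3,
                 "total_volume_mm3": 10.0, "max_volume_mm3": 6.0}]
        report = aggregate_report(rows)
        total = report.rows[report.rows["compartment"] == "total"].iloc[0]
        assert (total["number"], total["total_volume_mm3"], total["max_volume_mm3"]) == (3, 10.0, 6.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        data=st.lists(
            st.tuples(st.integers(0, 60), st.floats(0, 500), st.floats(0, 200)),
            min_size=1,
            max_size=4,
        )
    )
    def test_totals_consistency_random_rows(self, data):
        rows = [
            {
                "site": "femoral",
                "compartment": f"c{i}",
                "number": n,
                "total_volume_mm3": tv,
                "max_volume_mm3": min(mv, tv),
            }
            for i, (n, tv, mv) in enumerate(data)
        ]
        report = aggregate_report(rows)
        parts = report.rows[report.rows["compartment"] != "total"]
        total = report.rows[report.rows["compartment"] == "total"].iloc[0]
        assert total["number"] == parts["number"].sum()
        assert total["total_volume_mm3"] == pytest.approx(
            round(parts["total_volume_mm3"].sum(), 1), abs=0.11
        )
        assert total["max_volume_mm3"] >= parts["max_volume_mm3"].max() - 0.11


class TestCystDensity:
    def _band(self, n_vox, voxel=0.25):
        mask = np.zeros((50, 50, 50), bool)
        mask.ravel()[:n_vox] = True
        return ks.SubchondralBand(mask=mask, depth=10.0,
                                  reference_surface=mask, voxel_size=voxel)

    def test_zero_cysts_zero_density(self):
        rows = [{"site": "femoral", "compartment": "medial", "number": 0,
                 "total_volume_mm3": 0.0, "max_volume_mm3": 0.0}]
        assert cyst_density(aggregate_report(rows), self._band(64000)) == 0.0

    def test_arithmetic(self):
        rows = [{"site": "femoral", "compartment": "medial", "number": 10,
                 "total_volume_mm3": 50.0, "max_volume_mm3": 9.0}]
        band = self._band(64000)  # 64000 * 0.015625 = 1000 mm^3
        assert cyst_density(aggregate_report(rows), band) == pytest.approx(0.01)

    def test_invariant_under_voxel_refinement(self):
        """The same physical band at 0.25 and 0.125 mm voxels gives the
        same density within discretization tolerance."""
        rows = [{"site": "femoral", "compartment": "medial", "number": 4,
                 "total_volume_mm3": 8.0, "max_volume_mm3": 4.0}]
        report = aggregate_report(rows)
        coarse = self._band(8000, voxel=0.25)        # 125 mm^3
        mask_f = np.zeros((50, 80, 80), bool)
        mask_f.ravel()[: 8000 * 8] = True            # same physical volume
        fine = ks.SubchondralBand(mask=mask_f, depth=10.0,
                                  reference_surface=mask_f, voxel_size=0.125)
        d1 = cyst_density(report, coarse)
        d2 = cyst_density(report, fine)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_zero_band_volume_rejected(self):
        rows = [{"site": "femoral", "compartment": "medial", "number": 1,
                 "total_volume_mm3": 1.0, "max_volume_mm3": 1.0}]
        band = self._band(0)
        with pytest.raises(ValueError):
            cyst_density(aggregate_report(rows), band)
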