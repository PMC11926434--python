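import math

import numpy as np
import pytest

from vheetps.geometry import (
    BEVFootprint,
    arrange_beams,
    make_field,
    parallel_opposed,
    place_spots,
    project_to_bev,
    radiological_depth,
    single_beam,
)
from vheetps.phantom import ImageGrid, PhantomSpec, Structure, make_phantom


def square_footprint(extent_cells=20, res=2.0):
    """Square footprint covering [-20, 20] mm as 20x20 cells of 2 mm."""
    coords = (np.arange(extent_cells) - extent_cells / 2 + 0.5) * res
    return BEVFootprint(np.ones((extent_cells, extent_cells), bool), coords, coords, res)


def shapely_spot_oracle(footprint, margin, spacing, centroid):
    """Independent enumerate-and-filter oracle: union of footprint cell boxes,
    Euclidean buffer by margin, keep lattice points covered by the region."""
    from shapely.geometry import Point, box
    from shapely.ops import unary_union

    iu, iv = np.nonzero(footprint.mask)
    half = footprint.resolution_mm / 2.0
    region = unary_union(
        [
            box(
                footprint.u_coords_mm[i] - half,
                footprint.v_coords_mm[j] - half,
                footprint.u_coords_mm[i] + half,
                footprint.v_coords_mm[j] + half,
            )
            for i, j in zip(iu, iv)
        ]
    ).buffer(margin)
    count = 0
    for ku in range(-40, 41):
        for kv in range(-40, 41):
            p = Point(centroid[0] + ku * spacing, centroid[1] + kv * spacing)
            if region.covers(p) or region.distance(p) <= 1e-9:
                count += 1
    return count


class TestArrangeBeams:
    def test_five_beams_200_span(self):
        angles = arrange_beams(5, 200.0, 0.0)
        assert angles == [a % 360.0 for a in (-100.0, -50.0, 0.0, 50.0, 100.0)]

    def test_parallel_opposed(self):
        assert parallel_opposed(90.0) == [90.0, 270.0]

    def test_full_arc_pitch(self):
        angles = arrange_beams(15, 360.0)
        diffs = np.diff(sorted(angles))
        np.testing.assert_allclose(diffs, 24.0)
        assert len(set(angles)) == 15

    def test_single_beam(self):
        assert single_beam(37.0) == [37.0]
        assert arrange_beams(1, 200.0, 42.0) == [42.0]

    def test_invalid_span(self):
        with pytest.raises(ValueError):
            arrange_beams(5, 0.0)
        with pytest.raises(ValueError):
            arrange_beams(5, 400.0)

    def test_center_shift_is_pure_rotation(self):
        base = arrange_beams(7, 200.0, 0.0)
        shifted = arrange_beams(7, 200.0, 30.0)
        deltas = {round((s - b) % 360.0, 9) for s, b in zip(shifted, base)}
        assert deltas == {30.0}


class TestRadiologicalDepth:
    def test_uniform_water(self, water_box_small):
        grid = water_box_small.grid
        field = make_field(0.0, grid.center_mm())
        wepl = radiological_depth(grid, field)
        # beam travels +y; voxel j is (j + 0.5) * 2 mm beyond entry
        for j in (0, 7, 19):
            assert wepl[10, j, 10] == pytest.approx((j + 0.5) * 2.0, abs=1e-9)

    def test_slab_then_water(self):
        # 50 mm slab of density 0.3 (j < 25 at 2 mm), then water
        density = np.ones((20, 60, 20))
        density[:, :25, :] = 0.3
        grid = ImageGrid((20, 60, 20), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), density)
        field = make_field(0.0, grid.center_mm())
        wepl = radiological_depth(grid, field)
        # voxel centre 29 mm into the water section (y = 79 mm -> j = 39)
        assert wepl[10, 39, 10] == pytest.approx(0.3 * 50.0 + 29.0, abs=1e-9)

    def test_random_grid_vs_dense_marching_oracle(self, rng):
        density = rng.uniform(0.0, 1.5, size=(20, 20, 20))
        grid = ImageGrid((20, 20, 20), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), density)
        field = make_field(33.0, grid.center_mm())
        wepl = radiological_depth(grid, field)
        d = field.direction
        step = 0.1
        for _ in range(20):
            i, j, k = (int(v) for v in rng.integers(0, 20, 3))
            p = np.array([(i + 0.5) * 2.0, (j + 0.5) * 2.0, (k + 0.5) * 2.0])
            # march backwards until outside the grid
            acc = 0.0
            t = 0.0
            while True:
                t += step
                q = p - (t - step / 2.0) * d
                idx = np.floor(q / 2.0).astype(int)
                if np.any(idx < 0) or np.any(idx >= 20):
                    break
                acc += density[idx[0], idx[1], idx[2]] * step
            assert abs(acc - wepl[i, j, k]) < 0.5

    def test_non_unit_axis_rejected(self, water_box_small):
        field = make_field(0.0, water_box_small.grid.center_mm())
        object.__setattr__(field, "direction", np.array([0.0, 2.0, 0.0]))
        with pytest.raises(ValueError):
            radiological_depth(water_box_small.grid, field)


class TestProjectToBev:
    def test_cuboid_axis_aligned(self, water_box_small):
        grid = water_box_small.grid
        ptv = water_box_small["ptv"]
        field = make_field(0.0, grid.center_mm())
        fp = project_to_bev(ptv, field, grid)
        # 20 mm cuboid -> 10x10 cells at 2 mm resolution
        assert fp.mask.sum() == 100
        iu, iv = np.nonzero(fp.mask)
        assert fp.u_coords_mm[iu].max() - fp.u_coords_mm[iu].min() == pytest.approx(18.0)

    def test_sphere_projects_to_disc(self):
        grid_shape = (40, 40, 40)
        xx, yy, zz = np.meshgrid(*[(np.arange(40) + 0.5) * 2.0] * 3, indexing="ij")
        mask = (xx - 40) ** 2 + (yy - 40) ** 2 + (zz - 40) ** 2 <= 15.0**2
        grid = ImageGrid(grid_shape, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), np.ones(grid_shape))
        s = Structure("sphere", mask, "target")
        field = make_field(0.0, (40.0, 40.0, 40.0))
        fp = project_to_bev(s, field, grid)
        area = fp.mask.sum() * fp.resolution_mm**2
        assert area == pytest.approx(np.pi * 15.0**2, rel=0.1)

    def test_rotated_cuboid_footprint_bounded(self, water_box_small):
        grid = water_box_small.grid
        ptv = water_box_small["ptv"]
        face = 20.0 * 20.0
        diagonal = 20.0 * math.sqrt(2) * 20.0
        fp = project_to_bev(ptv, make_field(45.0, grid.center_mm()), grid)
        area = fp.mask.sum() * fp.resolution_mm**2
        assert face * 0.9 <= area <= diagonal * 1.1

    def test_empty_structure_rejected(self, water_box_small):
        grid = water_box_small.grid
        s = Structure("empty", np.zeros(grid.shape, bool), "oar")
        with pytest.raises(ValueError):
            project_to_bev(s, make_field(0.0, grid.center_mm()), grid)


class TestPlaceSpots:
    field = make_field(0.0, (0.0, 0.0, 0.0))

    def test_square_footprint_against_oracle(self):
        fp = square_footprint()
        for spacing in (6.0, 4.0, 12.0):
            sg = place_spots(fp, spacing_mm=spacing, field=self.field, sigma0_mm=4.0, margin_mm=5.0)
            assert len(sg) == shapely_spot_oracle(fp, 5.0, spacing, fp.centroid())

    def test_frozen_counts(self):
        # oracle-derived counts for the 40x40 mm square footprint, margin 5
        fp = square_footprint()
        n6 = len(place_spots(fp, 6.0, self.field, 4.0, margin_mm=5.0))
        n4 = len(place_spots(fp, 4.0, self.field, 4.0, margin_mm=5.0))
        assert (n6, n4) == (77, 165)
        # density scales roughly with (spacing ratio)^2 = 2.25
        assert n4 / n6 == pytest.approx(2.25, rel=0.1)

    def test_single_cell_margin_zero(self):
        fp = BEVFootprint(np.ones((1, 1), bool), np.array([3.0]), np.array([-1.0]), 2.0)
        sg = place_spots(fp, spacing_mm=2.0, field=self.field, sigma0_mm=4.0, margin_mm=0.0)
        assert len(sg) == 1
        np.testing.assert_allclose(sg.positions_mm[0], [3.0, -1.0])

    def test_monotone_in_spacing_and_margin(self):
        fp = square_footprint()
        counts = [
            len(place_spots(fp, s, self.field, 4.0, margin_mm=5.0)) for s in (2.0, 4.0, 6.0, 8.0, 12.0)
        ]
        assert counts == sorted(counts, reverse=True)
        counts_m = [
            len(place_spots(fp, 6.0, self.field, 4.0, margin_mm=m)) for m in (0.0, 2.0, 5.0, 10.0)
        ]
        assert counts_m == sorted(counts_m)

    def test_coverage_property(self):
        """Every footprint cell centre is within spacing*sqrt(2)/2 of a spot."""
        fp = square_footprint()
        for spacing in (4.0, 6.0):
            sg = place_spots(fp, spacing, self.field, 4.0, margin_mm=5.0)
            iu, iv = np.nonzero(fp.mask)
            cells = np.column_stack([fp.u_coords_mm[iu], fp.v_coords_mm[iv]])
            d = np.sqrt(((cells[:, None, :] - sg.positions_mm[None, :, :]) ** 2).sum(-1)).min(1)
            assert d.max() <= spacing * math.sqrt(2) / 2 + 1e-9

    def test_all_spots_within_dilated_footprint(self):
        fp = square_footprint()
        sg = place_spots(fp, 6.0, self.field, 4.0, margin_mm=5.0)
        # square region is [-20, 20]^2; margin 5
        for u, v in sg.positions_mm:
            du = max(abs(u) - 20.0, 0.0)
            dv = max(abs(v) - 20.0, 0.0)
            assert math.hypot(du, dv) <= 5.0 + 1e-9

    def test_empty_footprint_rejected(self):
        fp = BEVFootprint(np.zeros((2, 2), bool), np.array([0.0, 2.0]), np.array([0.0, 2.0]), 2.0)
        with pytest.raises(ValueError):
            place_spots(fp, 6.0, self.field, 4.0)

    def test_lattice_property(self):
        fp = square_footprint()
        sg = place_spots(fp, 6.0, self.field, 4.0, margin_mm=5.0)
        rel = (sg.positions_mm - np.asarray(fp.centroid())) / 6.0
        np.testing.assert_allclose(rel, np.round(rel), atol=1e-9)


class TestEndToEndGeometry:
    def test_wepl_on_density_one_phantom(self, water_box_small):
        grid = water_box_small.grid
        for gantry in (0.0, 90.0, 37.0):
            field = make_field(gantry, grid.center_mm())
            wepl = radiological_depth(grid, field)
            # geometric depth from box entry along the ray
            d = field.direction
            i, j, k = 10, 10, 10
            p = np.array([(i + 0.5) * 2.0, (j + 0.5) * 2.0, (k + 0.5) * 2.0])
            ts = []
            for a in range(3):
                if abs(d[a]) > 1e-12:
                    ts.extend([(0.0 - p[a]) / d[a], (40.0 - p[a]) / d[a]])
            t_enter = max(t for t in ts if t < 0)
            assert wepl[i, j, k] == pytest.approx(-t_enter, abs=1e-9)
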