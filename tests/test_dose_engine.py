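import numpy as np
import pytest
import scipy.sparse as sp

from vheetps.base_data import BeamEnergySpec, generate_analytic_base_data, idd_at, sigma_total
from vheetps.dose_engine import (
    DoseDistribution,
    PencilBeam,
    compute_influence,
    load_influence,
    save_influence,
    spot_dose,
    total_dose,
)
from vheetps.geometry import SpotGrid, make_field, radiological_depth
from vheetps.phantom import ImageGrid


def brute_force_spot_dose(grid, field, u0, v0, base, sigma0, cutoff=3.5):
    """Per-voxel triple loop evaluating the pencil-beam formula directly."""
    wepl = radiological_depth(grid, field)
    out = np.zeros(grid.shape)
    cx, cy, cz = grid.voxel_centers()
    iso = field.isocenter_mm
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            for k in range(grid.shape[2]):
                p = np.array([cx[i], cy[j], cz[k]]) - iso
                u = float(p @ field.bev_u)
                v = float(p @ field.bev_v)
                d = wepl[i, j, k]
                s = float(sigma_total(sigma0, d, base))
                r2 = (u - u0) ** 2 + (v - v0) ** 2
                if r2 <= (cutoff * s) ** 2:
                    out[i, j, k] = (
                        float(idd_at(base, d)) * np.exp(-r2 / (2 * s * s)) / (2 * np.pi * s * s)
                    )
    return out


@pytest.fixture(scope="module")
def toy_grid():
    return ImageGrid((20, 20, 20), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), np.ones((20, 20, 20)))


class TestSpotDose:
    def test_matches_brute_force_oracle(self, toy_grid, base200, rng):
        """<= 1e-12 relative agreement with the per-voxel double loop."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            gantry = float(r.uniform(0, 360))
            field = make_field(gantry, toy_grid.center_mm())
            dmap = radiological_depth(toy_grid, field)
            for _ in range(2):
                u0, v0 = (float(x) for x in r.uniform(-10, 10, 2))
                pb = PencilBeam(0, field, u0, v0, 200.0, 4.0)
                got = spot_dose(pb, toy_grid, dmap, base200).toarray().reshape(toy_grid.shape)
                want = brute_force_spot_dose(toy_grid, field, u0, v0, base200, 4.0)
                np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-300)

    def test_lateral_mass_conservation(self, base200):
        """Slice sum x voxel area ~ IDD(depth) within 1% (3.5 sigma keeps
        99.8% of the Gaussian mass) at every tabulated slice depth."""
        grid = ImageGrid((60, 40, 60), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), np.ones((60, 40, 60)))
        field = make_field(0.0, grid.center_mm())
        dmap = radiological_depth(grid, field)
        pb = PencilBeam(0, field, 0.0, 0.0, 200.0, 4.0)
        dose = spot_dose(pb, grid, dmap, base200).toarray().reshape(grid.shape)
        area = grid.spacing_mm[0] * grid.spacing_mm[2]
        for j in range(grid.shape[1]):
            depth = (j + 0.5) * grid.spacing_mm[1]
            mass = dose[:, j, :].sum() * area
            assert mass == pytest.approx(float(idd_at(base200, depth)), rel=0.01)

    def test_outside_cutoff_exactly_zero(self, toy_grid, base200):
        field = make_field(0.0, toy_grid.center_mm())
        dmap = radiological_depth(toy_grid, field)
        pb = PencilBeam(0, field, 500.0, 0.0, 200.0, 4.0)
        assert spot_dose(pb, toy_grid, dmap, base200).nnz == 0

    def test_missing_base_data_rejected(self, toy_grid):
        field = make_field(0.0, toy_grid.center_mm())
        pb = PencilBeam(0, field, 0.0, 0.0, 200.0, 4.0)
        with pytest.raises(ValueError, match="base data"):
            spot_dose(pb, toy_grid, np.zeros(toy_grid.shape), None)

    def test_monotone_blur_with_depth(self, base200):
        """Lateral RMS width of a single spot is non-decreasing with depth."""
        grid = ImageGrid((40, 60, 40), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), np.ones((40, 60, 40)))
        field = make_field(0.0, grid.center_mm())
        dmap = radiological_depth(grid, field)
        pb = PencilBeam(0, field, 0.0, 0.0, 200.0, 4.0)
        dose = spot_dose(pb, grid, dmap, base200).toarray().reshape(grid.shape)
        x = (np.arange(40) + 0.5) * 2.0 - 40.0
        widths = []
        for j in range(0, 60, 5):
            profile = dose[:, j, 20]
            if profile.sum() <= 0:
                continue
            widths.append(np.sqrt((profile * x**2).sum() / profile.sum()))
        assert all(b >= a - 1e-9 for a, b in zip(widths, widths[1:]))


class TestInfluence:
    def _spot_grids(self, grid, base, gantries, positions):
        sgs, bases = [], []
        for g in gantries:
            field = make_field(g, grid.center_mm())
            sgs.append(SpotGrid(field, np.asarray(positions, float), 4.0, 5.0, 4.0))
            bases.append(base)
        return sgs, bases

    def test_single_spot_equals_column(self, toy_grid, base200):
        sgs, bases = self._spot_grids(toy_grid, base200, [0.0], [(0.0, 0.0)])
        infl = compute_influence(sgs, toy_grid, bases)
        field = sgs[0].field
        dmap = radiological_depth(toy_grid, field)
        col = spot_dose(PencilBeam(0, field, 0.0, 0.0, 200.0, 4.0), toy_grid, dmap, base200)
        np.testing.assert_allclose(infl.matrix.toarray(), col.toarray())

    def test_column_count(self, toy_grid, base200):
        sgs, bases = self._spot_grids(
            toy_grid, base200, [0.0, 120.0, 240.0], [(0.0, 0.0), (4.0, 0.0), (0.0, 4.0)]
        )
        infl = compute_influence(sgs, toy_grid, bases)
        assert infl.n_spots == 9
        assert len(infl.spot_table) == 9

    def test_field_permutation_invariance(self, toy_grid, base200):
        positions = [(0.0, 0.0), (4.0, 0.0)]
        sgs, bases = self._spot_grids(toy_grid, base200, [0.0, 90.0], positions)
        infl_a = compute_influence(sgs, toy_grid, bases)
        infl_b = compute_influence(sgs[::-1], toy_grid, bases[::-1])
        w = np.array([1.0, 2.0, 3.0, 4.0])
        dose_a = total_dose(infl_a, w)
        dose_b = total_dose(infl_b, np.r_[w[2:], w[:2]])
        np.testing.assert_allclose(dose_a.values, dose_b.values, rtol=1e-12)

    def test_duplicate_spots_rejected(self, toy_grid, base200):
        field = make_field(0.0, toy_grid.center_mm())
        with pytest.raises(ValueError, match="unique"):
            SpotGrid(field, np.array([(0.0, 0.0), (0.0, 0.0)]), 4.0, 5.0, 4.0)

    def test_parallel_opposed_symmetry(self, base200):
        """Mirrored spots on opposed lateral fields give an x-mirror-symmetric
        dose on a symmetric phantom."""
        grid = ImageGrid((30, 30, 30), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0), np.ones((30, 30, 30)))
        f90 = make_field(90.0, grid.center_mm())
        f270 = make_field(270.0, grid.center_mm())
        sg90 = SpotGrid(f90, np.array([(3.0, 1.0)]), 4.0, 5.0, 4.0)
        sg270 = SpotGrid(f270, np.array([(-3.0, 1.0)]), 4.0, 5.0, 4.0)
        infl = compute_influence([sg90, sg270], grid, [base200, base200])
        dose = total_dose(infl, np.ones(2)).values
        np.testing.assert_allclose(dose, dose[::-1, :, :], rtol=1e-6, atol=1e-12)


class TestTotalDose:
    def _influence(self, toy_grid, base200):
        field = make_field(0.0, toy_grid.center_mm())
        sg = SpotGrid(field, np.array([(0.0, 0.0), (6.0, 0.0)]), 6.0, 5.0, 4.0)
        return compute_influence([sg], toy_grid, [base200])

    def test_zero_weights(self, toy_grid, base200):
        infl = self._influence(toy_grid, base200)
        assert total_dose(infl, np.zeros(2)).values.sum() == 0.0

    def test_linearity(self, toy_grid, base200):
        infl = self._influence(toy_grid, base200)
        w = np.array([1.0, 2.5])
        np.testing.assert_allclose(
            total_dose(infl, 2 * w).values, 2 * total_dose(infl, w).values, rtol=1e-12
        )

    def test_superposition(self, toy_grid, base200):
        infl = self._influence(toy_grid, base200)
        w1, w2 = np.array([1.0, 0.5]), np.array([0.25, 2.0])
        np.testing.assert_allclose(
            total_dose(infl, w1 + w2).values,
            total_dose(infl, w1).values + total_dose(infl, w2).values,
            rtol=1e-12,
        )

    def test_negative_weight_rejected(self, toy_grid, base200):
        infl = self._influence(toy_grid, base200)
        with pytest.raises(ValueError):
            total_dose(infl, np.array([1.0, -0.1]))

    def test_weight_length_checked(self, toy_grid, base200):
        infl = self._influence(toy_grid, base200)
        with pytest.raises(ValueError):
            total_dose(infl, np.ones(3))


class TestPersistence:
    def test_hdf5_round_trip(self, toy_grid, base200, tmp_path):
        field = make_field(10.0, toy_grid.center_mm())
        sg = SpotGrid(field, np.array([(0.0, 0.0), (4.0, 4.0)]), 4.0, 5.0, 4.0)
        infl = compute_influence([sg], toy_grid, [base200])
        save_influence(infl, tmp_path / "infl.h5")
        loaded = load_influence(tmp_path / "infl.h5")
        assert (loaded.matrix != infl.matrix).nnz == 0
        assert loaded.spot_table == infl.spot_table
        assert loaded.grid.shape == toy_grid.shape
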