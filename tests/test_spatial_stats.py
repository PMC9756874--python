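"""IDW interpolation, density merging and the association statistics."""

import numpy as np
import pytest
from scipy import stats

from rewildscape import spatial_stats as sps
from rewildscape import landcover_change as lcc
from rewildscape.raster import GridMismatchError, Raster


def _surface(grid, data, mask=None):
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    arr = np.where(mask, data, np.nan)
    return sps.DensitySurface("test", grid.like(arr, nodata=np.nan), mask)


class TestIdw:
    def test_single_sample_constant_surface(self, small_grid):
        out = sps.idw_interpolate(np.array([[2500.0, 2500.0]]), np.array([7.0]), small_grid)
        np.testing.assert_allclose(out.raster.data, 7.0)

    def test_exact_at_coincident_node(self, small_grid):
        # (50, 4950) is the centre of cell (0, 0)
        pts = np.array([[50.0, 4950.0], [4000.0, 1000.0]])
        out = sps.idw_interpolate(pts, np.array([3.0, 9.0]), small_grid)
        assert out.raster.data[0, 0] == pytest.approx(3.0)

    @pytest.mark.parametrize("power", [1.0, 2.0, 3.5])
    def test_midpoint_is_mean_for_any_power(self, small_grid, power):
        # samples symmetric about the centre of cell (24, 24) at (2450, 2550)
        pts = np.array([[1450.0, 2550.0], [3450.0, 2550.0]])
        out = sps.idw_interpolate(pts, np.array([2.0, 10.0]), small_grid, power=power)
        assert out.raster.data[24, 24] == pytest.approx(6.0)

    def test_bounded_by_sample_range(self, small_grid):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 5000, (8, 2))
        vals = rng.uniform(1, 20, 8)
        out = sps.idw_interpolate(pts, vals, small_grid)
        assert np.nanmin(out.raster.data) >= vals.min() - 1e-9
        assert np.nanmax(out.raster.data) <= vals.max() + 1e-9

    def test_mask_clips_surface(self, small_grid):
        mask = np.zeros(small_grid.shape, dtype=bool)
        mask[:10, :10] = True
        out = sps.idw_interpolate(
            np.array([[2500.0, 2500.0]]), np.array([4.0]), small_grid, mask=mask
        )
        assert np.isnan(out.raster.data[40, 40])
        assert out.raster.data[5, 5] == pytest.approx(4.0)

    def test_no_samples_rejected(self, small_grid):
        with pytest.raises(sps.NoDataError):
            sps.idw_interpolate(np.empty((0, 2)), np.empty(0), small_grid)


class TestMergeDensities:
    def test_additive_identity_and_commutativity(self, small_grid):
        rng = np.random.default_rng(1)
        a = _surface(small_grid, rng.uniform(0, 5, small_grid.shape))
        zero = _surface(small_grid, np.zeros(small_grid.shape))
        merged = sps.merge_densities([a, zero])
        np.testing.assert_allclose(merged.raster.data, a.raster.data)
        b = _surface(small_grid, rng.uniform(0, 5, small_grid.shape))
        ab = sps.merge_densities([a, b]).raster.data
        ba = sps.merge_densities([b, a]).raster.data
        np.testing.assert_array_equal(ab, ba)

    def test_three_uniform_layers(self, small_grid):
        layers = [_surface(small_grid, np.full(small_grid.shape, v)) for v in (1, 2, 3)]
        merged = sps.merge_densities(layers)
        np.testing.assert_allclose(merged.raster.data, 6.0)

    def test_nodata_zero_where_any_valid(self, small_grid):
        m1 = np.zeros(small_grid.shape, bool)
        m1[:25] = True
        m2 = ~m1
        a = _surface(small_grid, np.full(small_grid.shape, 2.0), m1)
        b = _surface(small_grid, np.full(small_grid.shape, 5.0), m2)
        merged = sps.merge_densities([a, b])
        assert merged.raster.data[0, 0] == pytest.approx(2.0)
        assert merged.raster.data[30, 0] == pytest.approx(5.0)
        assert merged.mask.all()

    def test_grid_mismatch_rejected(self, small_grid):
        other = Raster(np.zeros((50, 50)), xmin=1.0, ymax=5000.0, resolution=100.0)
        a = _surface(small_grid, np.zeros(small_grid.shape))
        b = _surface(other, np.zeros(other.shape))
        with pytest.raises(GridMismatchError):
            sps.merge_densities([a, b])


class TestGlm:
    def test_constant_response_flat_fit(self, small_grid):
        dens = _surface(small_grid, np.full(small_grid.shape, 3.0))
        dist = small_grid.like(np.linspace(0, 10, small_grid.data.size).reshape(small_grid.shape))
        fit = sps.fit_density_distance_glm(dens, dist, family="gamma")
        assert fit.slope == pytest.approx(0.0, abs=1e-6)
        assert fit.pseudo_r2 == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("family", ["gamma", "inverse-gaussian"])
    def test_parameter_recovery(self, family):
        """Planted canonical-link coefficients recovered within 3 SE at n=5000."""
        rng = np.random.default_rng(12)
        n = 5000
        grid = Raster(np.zeros((50, 100)), xmin=0, ymax=5000, resolution=100)
        x = rng.uniform(0.2, 2.0, n)
        b0, b1 = 1.0, 0.6
        if family == "gamma":
            mu = 1.0 / (b0 + b1 * x)
            shape = 8.0
            y = rng.gamma(shape, mu / shape)
        else:
            mu = 1.0 / np.sqrt(b0 + b1 * x)
            lam = 50.0
            y = rng.wald(mu, lam)
        dens = _surface(grid, y.reshape(grid.shape))
        dist = grid.like(x.reshape(grid.shape))
        fit = sps.fit_density_distance_glm(dens, dist, family=family)
        assert abs(fit.intercept - b0) < 3 * fit.intercept_se
        assert abs(fit.slope - b1) < 3 * fit.slope_se

    def test_fitted_density_decreasing_when_decay_planted(self, small_grid):
        """Positive canonical slope => fitted mean falls with distance."""
        rng = np.random.default_rng(3)
        x = np.linspace(0.1, 5, small_grid.data.size)
        y = np.exp(-0.5 * x) * rng.gamma(20, 1 / 20, x.size) + 1e-3
        dens = _surface(small_grid, y.reshape(small_grid.shape))
        dist = small_grid.like(x.reshape(small_grid.shape))
        fit = sps.fit_density_distance_glm(dens, dist, family="gamma")
        assert fit.slope > 0  # inverse link: mu = 1/(b0+b1 x) decreasing
        mu_near = 1 / (fit.intercept + fit.slope * 0.5)
        mu_far = 1 / (fit.intercept + fit.slope * 4.0)
        assert mu_near > mu_far

    def test_zero_shift_logged(self, small_grid):
        vals = np.full(small_grid.shape, 2.0)
        vals[0, :10] = 0.0
        dens = _surface(small_grid, vals)
        dist = small_grid.like(np.linspace(0, 10, vals.size).reshape(small_grid.shape))
        with pytest.warns(UserWarning, match="shifted"):
            sps.fit_density_distance_glm(dens, dist, family="gamma")

    def test_too_few_cells_rejected(self, small_grid):
        mask = np.zeros(small_grid.shape, bool)
        mask[0, :5] = True
        dens = _surface(small_grid, np.full(small_grid.shape, 1.0), mask)
        dist = small_grid.like(np.ones(small_grid.shape))
        with pytest.raises(sps.InsufficientDataError):
            sps.fit_density_distance_glm(dens, dist)


class TestWelch:
    def test_identical_samples(self):
        r = sps.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_oracle(self):
        """Textbook Welch formula evaluated by hand on a = {1,2,3}, b = {1..6}."""
        a, b = [1.0, 2.0, 3.0], [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        na, nb = 3, 6
        t_hand = (np.mean(a) - np.mean(b)) / np.sqrt(va / na + vb / nb)
        df_hand = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
        p_hand = 2 * stats.t.sf(abs(t_hand), df_hand)
        r = sps.welch_t(a, b)
        assert r.statistic == pytest.approx(t_hand)
        assert r.df == pytest.approx(df_hand)
        assert r.p_value == pytest.approx(p_hand)

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        r1, r2 = sps.welch_t(a, b), sps.welch_t(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_insufficient_data(self):
        with pytest.raises(sps.InsufficientDataError):
            sps.welch_t([1.0], [1.0, 2.0])


class TestChiSquare:
    def test_homogeneous_table(self):
        assert sps.chi_square_2x2([[10, 10], [10, 10]]).statistic == pytest.approx(0.0)

    def test_succession_pixel_table(self):
        """Shortcut-formula value for the succession in/out pixel counts."""
        a, b, c, d = 1171.0, 1459.0, 433.0, 2793.0
        n = a + b + c + d
        shortcut = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        r = sps.chi_square_2x2([[1171, 1459], [433, 2793]])
        assert r.statistic == pytest.approx(shortcut)
        assert r.statistic == pytest.approx(704.7, abs=0.1)
        assert r.df == 1

    def test_scaling_property(self):
        t = np.array([[12, 34], [56, 7]])
        r1 = sps.chi_square_2x2(t)
        r10 = sps.chi_square_2x2(t * 10)
        assert r10.statistic == pytest.approx(10 * r1.statistic)

    def test_matches_shortcut_on_random_tables(self):
        """Pearson chi2 equals N(ad-bc)^2/(marginal product) to 1e-9."""
        rng = np.random.default_rng(11)
        for _ in range(2000):
            a, b, c, d = rng.integers(1, 500, 4).astype(float)
            n = a + b + c + d
            shortcut = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            got = sps.chi_square_2x2([[a, b], [c, d]]).statistic
            assert abs(got - shortcut) < 1e-9 * max(1.0, shortcut)

    def test_zero_marginal_degenerate(self):
        with pytest.raises(sps.DegenerateTableError):
            sps.chi_square_2x2([[0, 0], [5, 5]])


class TestClassSummaries:
    def _change(self, grid, pattern):
        return grid.like(np.asarray(pattern, dtype=int))

    def test_uniform_density_equal_means(self, small_grid):
        dens = _surface(small_grid, np.full(small_grid.shape, 5.0))
        cls = np.full(small_grid.shape, lcc.NONE_VALUE)
        cls[:10] = lcc.SS_VALUE
        cls[10:20] = lcc.IS_VALUE
        out = sps.class_density_summary(dens, self._change(small_grid, cls))
        assert out["SS"]["mean"] == pytest.approx(5.0)
        assert out["IS"]["mean"] == pytest.approx(5.0)
        assert out["SS"]["se"] == pytest.approx(0.0)

    def test_hand_built_six_cells(self):
        grid = Raster(np.zeros((2, 3)), xmin=0, ymax=200, resolution=100)
        dens = _surface(grid, np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]]))
        cls = grid.like(np.array([[1, 1, 2], [2, 0, 0]]))
        out = sps.class_density_summary(dens, cls)
        assert out["SS"]["mean"] == pytest.approx(1.5)   # cells 1, 2
        assert out["IS"]["mean"] == pytest.approx(3.5)   # cells 3, 4
        assert out["none"]["mean"] == pytest.approx(5.5)
        assert out["SS"]["n"] == 2

    def test_absent_class_omitted(self, small_grid):
        dens = _surface(small_grid, np.ones(small_grid.shape))
        cls = self._change(small_grid, np.full(small_grid.shape, lcc.NONE_VALUE))
        out = sps.class_density_summary(dens, cls)
        assert "SS" not in out and "IS" not in out

    def test_weighted_means_recompose_global_mean(self, small_grid):
        rng = np.random.default_rng(6)
        dens = _surface(small_grid, rng.uniform(0, 10, small_grid.shape))
        cls = self._change(small_grid, rng.integers(0, 3, small_grid.shape))
        out = sps.class_density_summary(dens, cls)
        total_n = sum(v["n"] for v in out.values())
        recomposed = sum(v["mean"] * v["n"] for v in out.values()) / total_n
        assert recomposed == pytest.approx(float(np.mean(dens.raster.data)))


class TestElevationByClass:
    def test_identical_elevation_null(self, small_grid):
        elev = small_grid.like(np.full(small_grid.shape, 600.0))
        cls = np.full(small_grid.shape, lcc.NONE_VALUE)
        cls[:10] = lcc.SS_VALUE
        cls[10:20] = lcc.IS_VALUE
        r = sps.elevation_by_class(
            elev, small_grid.like(cls), np.zeros(small_grid.shape, bool)
        )
        assert r.statistic == pytest.approx(0.0)

    def test_planted_contrast_detected(self, small_grid):
        rng = np.random.default_rng(2)
        elev = np.full(small_grid.shape, 0.0)
        cls = np.full(small_grid.shape, lcc.NONE_VALUE)
        cls[:10] = lcc.SS_VALUE
        cls[10:20] = lcc.IS_VALUE
        elev[:10] = rng.normal(400, 10, (10, 50))
        elev[10:20] = rng.normal(800, 10, (10, 50))
        r = sps.elevation_by_class(
            small_grid.like(elev), small_grid.like(cls), np.zeros(small_grid.shape, bool)
        )
        assert r.p_value < 1e-6
        assert r.means[0] < r.means[1]

    def test_everything_excluded_is_insufficient(self, small_grid):
        elev = small_grid.like(np.full(small_grid.shape, 500.0))
        cls = small_grid.like(np.full(small_grid.shape, lcc.SS_VALUE))
        with pytest.raises(sps.InsufficientDataError):
            sps.elevation_by_class(elev, cls, np.ones(small_grid.shape, bool))
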