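"""Semivariograms, ordinary kriging, LOO NRMSE, change fractions, grids."""

import io

import numpy as np
import pytest

from sundiv.geostat import (
    FAMILIES,
    DegenerateGeometryError,
    EmpiricalSemivariogram,
    GridSpec,
    KrigedSurface,
    NormalizationError,
    SemivariogramModel,
    change_fraction,
    default_grid,
    empirical_semivariogram,
    fit_semivariogram,
    krige_points,
    loo_nrmse,
    map_diversity,
    ordinary_krige,
    surface_to_frame,
    write_ascii_grid,
)


def simulate_gaussian_field(rng, n, model, extent=1000.0):
    """Draw a zero-mean field with the covariance implied by the model."""
    pts = rng.uniform(0, extent, (n, 2))
    d = np.linalg.norm(pts[:, None] - pts[None], axis=-1)
    cov = model.sill - model(d)
    cov[np.diag_indices_from(cov)] = model.sill
    L = np.linalg.cholesky(cov + 1e-9 * np.eye(n))
    return pts, L @ rng.standard_normal(n)


class TestEmpirical:
    def test_two_points(self):
        emp = empirical_semivariogram(np.array([[0, 0], [10, 0]]), np.array([0.0, 2.0]),
                                      n_bins=1, max_lag=20)
        assert emp.gamma_hat[0] == pytest.approx(2.0)    # (1/2)(2)^2
        assert emp.pair_counts[0] == 1

    def test_constant_field(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, (20, 2))
        emp = empirical_semivariogram(pts, np.full(20, 5.0))
        np.testing.assert_allclose(emp.gamma_hat, 0.0)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            empirical_semivariogram(np.zeros((4, 2)), np.arange(4.0))

    def test_tracks_known_model(self):
        """Binned estimates from a simulated spherical field track the model."""
        model = SemivariogramModel("spherical", 0.0, 1.0, 300.0)
        rng = np.random.default_rng(42)
        reps = []
        for _ in range(8):
            pts, z = simulate_gaussian_field(rng, 120, model)
            emp = empirical_semivariogram(pts, z, n_bins=8)
            reps.append(np.interp([100, 200, 300], emp.bin_centers, emp.gamma_hat))
        mean_gh = np.mean(reps, axis=0)
        np.testing.assert_allclose(mean_gh, model([100, 200, 300]), rtol=0.25)


class TestFit:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_exact_recovery(self, family):
        true = SemivariogramModel(family, 0.1, 1.0, 300.0)
        h = np.linspace(25, 900, 12)
        emp = EmpiricalSemivariogram(h, true(h), np.full(12, 40))
        best, fits = fit_semivariogram(emp)
        assert best.family == family
        assert best.nugget == pytest.approx(0.1, abs=0.01)
        assert best.partial_sill == pytest.approx(1.0, rel=0.01)
        assert best.range_ == pytest.approx(300.0, rel=0.01)
        assert all(f in fits for f in FAMILIES)

    def test_tie_breaks_canonical(self):
        # constant-sill bins: every family can fit exactly -> near-tied SSEs
        h = np.linspace(100, 900, 8)
        emp = EmpiricalSemivariogram(h, np.full(8, 1.0), np.full(8, 10))
        best, fits = fit_semivariogram(emp)
        sses = [fits[f].sse for f in FAMILIES if f in fits]
        assert best.family == "spherical"
        assert max(sses) < 1e-6

    def test_pure_nugget_flagged(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 1000, (80, 2))
        z = rng.standard_normal(80)
        emp = empirical_semivariogram(pts, z)
        best, _ = fit_semivariogram(emp)
        assert isinstance(best, SemivariogramModel)   # comparison still returns
        # white noise: the structured fraction is tiny (or the fit says so)
        assert best.nugget_dominated or best.partial_sill / best.sill < 0.5

    def test_needs_three_bins(self):
        emp = EmpiricalSemivariogram(np.array([1.0, 2.0]), np.array([1.0, 1.0]),
                                     np.array([3, 3]))
        with pytest.raises(ValueError):
            fit_semivariogram(emp)


class TestKriging:
    model = SemivariogramModel("spherical", 0.0, 1.0, 400.0)

    def test_constant_field_reproduced(self):
        rng = np.random.default_rng(2)
        pts = rng.uniform(0, 1000, (20, 2))
        preds = krige_points(pts, np.full(20, 3.7), self.model,
                             rng.uniform(0, 1000, (40, 2)))
        np.testing.assert_allclose(preds, 3.7, atol=1e-10)

    def test_exact_at_data_with_zero_nugget(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1000, (25, 2))
        z = np.sin(pts[:, 0] / 150)
        preds = krige_points(pts, z, self.model, pts)
        np.testing.assert_allclose(preds, z, atol=1e-9)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(0, 1000, (30, 2))
        z = rng.standard_normal(30)
        _, W = krige_points(pts, z, self.model, rng.uniform(0, 1000, (60, 2)),
                            return_weights=True)
        np.testing.assert_allclose(W.sum(axis=1), 1.0, atol=1e-10)

    def test_hand_built_system_oracle(self):
        """Weights for 3 collinear points match an explicit dense solve."""
        pts = np.array([[0.0, 0.0], [100.0, 0.0], [250.0, 0.0]])
        z = np.array([1.0, 2.0, 0.5])
        target = np.array([[160.0, 0.0]])
        m = SemivariogramModel("spherical", 0.05, 1.0, 300.0)
        preds, W = krige_points(pts, z, m, target, return_weights=True)
        # independent dense construction
        A = np.ones((4, 4))
        for i in range(3):
            for j in range(3):
                A[i, j] = m(np.linalg.norm(pts[i] - pts[j]))
        A[3, 3] = 0.0
        b = np.append([m(np.linalg.norm(p - target[0])) for p in pts], 1.0)
        lam = np.linalg.solve(A, b)
        np.testing.assert_allclose(W[0], lam[:3], atol=1e-10)
        assert preds[0] == pytest.approx(lam[:3] @ z, abs=1e-10)

    def test_duplicates_averaged_with_warning(self):
        pts = np.array([[0, 0], [0, 0], [100, 0], [200, 100]], dtype=float)
        z = np.array([1.0, 3.0, 5.0, 2.0])
        with pytest.warns(UserWarning, match="duplicate"):
            preds = krige_points(pts, z, self.model, np.array([[0.0, 0.0]]))
        assert preds[0] == pytest.approx(2.0, abs=1e-9)   # mean of 1 and 3

    def test_surface_grid_geometry(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 500, (15, 2))
        grid = default_grid(pts, cell_size=25.0)
        assert grid.cell_size == 25.0                     # 625 m^2 cells
        surf = ordinary_krige(pts, rng.standard_normal(15), self.model, grid)
        assert surf.values.shape == (grid.ny, grid.nx)
        assert np.isfinite(surf.values).all()
        lo = np.array(grid.origin)
        assert (lo <= pts.min(axis=0)).all()


class TestLOO:
    def test_constant_field_zero(self):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 1000, (12, 2))
        cv = loo_nrmse(pts, np.full(12, 1.5), TestKriging.model)
        assert cv.nrmse == 0.0

    def test_nrmse_is_rmse_over_range(self):
        rng = np.random.default_rng(60)
        pts = rng.uniform(0, 1000, (20, 2))
        z = rng.standard_normal(20)
        cv = loo_nrmse(pts, z, TestKriging.model)
        assert cv.nrmse == pytest.approx(cv.rmse / (z.max() - z.min()))
        assert cv.value_range == pytest.approx(z.max() - z.min())

    def test_white_noise_comparable_to_mean_predictor(self):
        rng = np.random.default_rng(7)
        ratios = []
        for _ in range(5):
            pts = rng.uniform(0, 1000, (50, 2))
            z = rng.standard_normal(50)
            emp = empirical_semivariogram(pts, z)
            model, _ = fit_semivariogram(emp)
            cv = loo_nrmse(pts, z, model)
            mean_nrmse = np.sqrt(np.mean((z - z.mean()) ** 2)) / (z.max() - z.min())
            ratios.append(cv.nrmse / mean_nrmse)
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.2)

    def test_structured_field_beats_mean_predictor(self):
        true = SemivariogramModel("spherical", 0.05, 1.0, 400.0)
        wins = 0
        for s in range(6):
            rng = np.random.default_rng(200 + s)
            pts, z = simulate_gaussian_field(rng, 60, true)
            emp = empirical_semivariogram(pts, z)
            model, _ = fit_semivariogram(emp)
            cv = loo_nrmse(pts, z, model)
            mean_nrmse = np.sqrt(np.mean((z - z.mean()) ** 2)) / (z.max() - z.min())
            wins += cv.nrmse < mean_nrmse
        assert wins == 6


class TestChangeFraction:
    def _surface(self, vals):
        grid = GridSpec((0.0, 0.0), 25.0, 4, 2)
        model = SemivariogramModel("spherical", 0.0, 1.0, 100.0)
        return KrigedSurface(grid, np.asarray(vals, dtype=float), model)

    def test_identical(self):
        a = self._surface(np.ones((2, 4)))
        assert change_fraction(a, a, "increase") == 0.0
        assert change_fraction(a, a, "decrease") == 0.0

    def test_uniform_shift(self):
        a = self._surface(np.ones((2, 4)))
        b = self._surface(np.ones((2, 4)) + 1)
        assert change_fraction(a, b, "increase") == 1.0
        assert change_fraction(a, b, "decrease") == 0.0

    def test_half_and_half(self):
        base = np.ones((2, 4))
        shifted = base.copy()
        shifted[:, :2] += 1.0
        assert change_fraction(self._surface(base), self._surface(shifted),
                               "increase") == 0.5

    def test_epsilon_threshold(self):
        a = self._surface(np.ones((2, 4)))
        b = self._surface(np.ones((2, 4)) + 0.1)
        assert change_fraction(a, b, "increase", epsilon=0.5) == 0.0

    def test_geometry_mismatch(self):
        a = self._surface(np.ones((2, 4)))
        grid = GridSpec((0.0, 0.0), 50.0, 4, 2)
        b = KrigedSurface(grid, np.ones((2, 4)), a.model)
        with pytest.raises(ValueError):
            change_fraction(a, b, "increase")


class TestAsciiGrid:
    def test_round_trip_text(self, tmp_path):
        grid = GridSpec((10.0, 20.0), 25.0, 3, 2)
        vals = np.arange(6, dtype=float).reshape(2, 3)
        surf = KrigedSurface(grid, vals,
                             SemivariogramModel("spherical", 0.0, 1.0, 100.0))
        p = tmp_path / "s.asc"
        write_ascii_grid(surf, p)
        lines = p.read_text().splitlines()
        header = dict(l.split() for l in lines[:6])
        assert header["ncols"] == "3" and header["nrows"] == "2"
        assert float(header["cellsize"]) == 25.0
        parsed = np.loadtxt(io.StringIO("\n".join(lines[6:])))
        np.testing.assert_allclose(parsed, vals)

    def test_tidy_frame(self):
        grid = GridSpec((0.0, 0.0), 10.0, 2, 2)
        surf = KrigedSurface(grid, np.array([[1.0, 2.0], [3.0, 4.0]]),
                             SemivariogramModel("spherical", 0.0, 1.0, 100.0))
        df = surface_to_frame(surf)
        assert len(df) == 4
        # raster order: top row first
        assert df.iloc[0]["y"] > df.iloc[3]["y"]


class TestMapDiversity:
    def test_epoch_surfaces_and_cv(self, small_scenario_table):
        t = small_scenario_table
        out = map_diversity(t, "alpha_bar", 1.0, years=[t.years[0]], cell_size=150.0)
        assert list(out) == [t.years[0]]                # single epoch, no change map
        m = out[t.years[0]]
        assert np.isfinite(m["surface"].values).all()
        assert m["cv"].nrmse >= 0
        # grid covers the plot bounding box
        xy = t.coordinates()
        g = m["surface"].grid
        assert g.origin[0] <= xy[:, 0].min()
        assert g.origin[0] + g.nx * g.cell_size >= xy[:, 0].max()

    def test_temporal_rho_surface(self, small_scenario_table):
        t = small_scenario_table
        out = map_diversity(t, "temporal_rho", 1.0, years=[t.years[-1]],
                            cell_size=150.0)
        vals = out[t.years[-1]]["surface"].values
        assert np.isfinite(vals).all()

    def test_directional_change_recovered(self):
        """A known regional alpha increase shows up in the change fraction."""
        from sundiv.synthetic import homogenization_scenario, simulate_scenario

        tab = simulate_scenario(homogenization_scenario(1.0, seed=8))
        out = map_diversity(tab, "rho_bar", 1.0, years=[1986, 2014], cell_size=250.0)
        frac_up = change_fraction(out[1986]["surface"], out[2014]["surface"],
                                  "increase")
        assert frac_up > 0.5          # homogenization: representativeness rises
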