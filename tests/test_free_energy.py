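"""WHAM, Boltzmann inversion, minima and compaction shifts."""

import numpy as np
import pytest

from pflattice.free_energy import (ConvergenceError, CoverageError,
                                   FreeEnergySurface, compaction_shift,
                                   default_rise_edges, dg_between,
                                   histogram_fes, locate_minimum, marginalize,
                                   wham)
from pflattice.lattice import UmbrellaWindow, default_params, sample_umbrella


@pytest.fixture(scope="module")
def gaussian_pmf():
    """Histogram FES of 1e5 Gaussian samples (harmonic PMF)."""
    rng = np.random.default_rng(3)
    samples = rng.normal(8.3, 0.05, 100_000)
    return samples, histogram_fes(samples, default_rise_edges())


class TestWham:
    def test_single_unbiased_window_equals_boltzmann_inversion(self, gaussian_pmf):
        samples, direct = gaussian_pmf
        fes = wham([UmbrellaWindow(8.3, 0.0, samples)], default_rise_edges(),
                   n_bootstrap=0)
        mask = np.isfinite(fes.G) & np.isfinite(direct.G)
        np.testing.assert_allclose(fes.G[mask], direct.G[mask], atol=1e-12)

    def test_harmonic_curvature_recovered(self, gaussian_pmf):
        # G(x) = (x - mu)^2 / (2 s^2): curvature 1/s^2 within 5% at n = 1e5
        samples, fes = gaussian_pmf
        c = fes.centers[0]
        sel = np.isfinite(fes.G) & (np.abs(c - 8.3) < 0.1)
        coeff = np.polyfit(c[sel], fes.G[sel], 2)
        assert 2 * coeff[0] == pytest.approx(1.0 / 0.05**2, rel=0.05)

    def test_flat_samples_give_flat_pmf(self):
        rng = np.random.default_rng(4)
        windows = [UmbrellaWindow(8.3, 0.0, rng.uniform(8.0, 8.6, 200_000))]
        fes = wham(windows, np.linspace(8.05, 8.55, 26), n_bootstrap=0)
        assert np.nanmax(fes.G) < 0.1  # noise envelope only

    def test_synthetic_gdp_minimum(self):
        p = default_params("GDP")
        windows = sample_umbrella(p, np.arange(7.95, 8.41, 0.05), 2000.0,
                                  3000, seed=5)
        fes = wham(windows, default_rise_edges(), n_bootstrap=10, seed=1)
        pos = locate_minimum(fes)
        assert pos[0] == pytest.approx(8.15, abs=0.0025)  # half a bin
        assert np.nanmean(fes.G_err) > 0

    def test_duplicating_samples_leaves_pmf_unchanged(self):
        rng = np.random.default_rng(6)
        p = default_params("GTP", k_ext=367.0)
        windows = sample_umbrella(p, [8.30, 8.40, 8.50], 3000.0, 2000, seed=7)
        doubled = [UmbrellaWindow(w.center, w.k_bias,
                                  np.concatenate([w.samples, w.samples]))
                   for w in windows]
        edges = default_rise_edges()
        a = wham(windows, edges, n_bootstrap=0)
        b = wham(doubled, edges, n_bootstrap=0)
        mask = np.isfinite(a.G) & np.isfinite(b.G)
        np.testing.assert_allclose(a.G[mask], b.G[mask], atol=1e-6)

    def test_disconnected_windows_raise_coverage_error(self):
        rng = np.random.default_rng(8)
        windows = [UmbrellaWindow(8.0, 1000.0, rng.normal(8.0, 0.01, 500)),
                   UmbrellaWindow(8.5, 1000.0, rng.normal(8.5, 0.01, 500))]
        with pytest.raises(CoverageError):
            wham(windows, default_rise_edges(), n_bootstrap=0)

    def test_nonconvergence_reports_diagnostics(self):
        rng = np.random.default_rng(9)
        windows = sample_umbrella(default_params("GDP"), [8.10, 8.15, 8.20],
                                  1000.0, 1000, seed=10)
        with pytest.raises(ConvergenceError, match="iterations"):
            wham(windows, default_rise_edges(), tol=1e-14, max_iter=2,
                 n_bootstrap=0)


class TestSurfaces:
    def test_min_reference_enforced(self):
        fes = FreeEnergySurface(edges=[np.array([0.0, 1.0, 2.0])],
                                G=np.array([5.0, 7.0]))
        assert np.nanmin(fes.G) == 0.0

    def test_histogram_fes_flags_empty_bins(self):
        samples = np.array([0.5] * 100 + [2.5] * 100)
        fes = histogram_fes(samples, np.array([0.0, 1.0, 2.0, 3.0]))
        assert np.isnan(fes.G[1])
        assert np.isfinite(fes.G[0]) and np.isfinite(fes.G[2])

    def test_delta_samples_single_zero_bin(self):
        fes = histogram_fes(np.full(100, 8.3), default_rise_edges())
        assert np.nansum(fes.G) == 0.0 and np.isfinite(fes.G).sum() == 1

    def test_bivariate_gaussian_axis_ratio(self):
        # elliptic isocontours with axis ratio sqrt((1+rho)/(1-rho))
        rho = 0.6
        rng = np.random.default_rng(10)
        xy = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], 400_000)
        edges = np.linspace(-3, 3, 61)
        fes = histogram_fes(xy, [edges, edges])
        p = fes.density()
        c = fes.centers[0]
        cov = np.zeros((2, 2))
        mx = (p.sum(axis=1) * c).sum()
        my = (p.sum(axis=0) * c).sum()
        cov[0, 0] = (p.sum(axis=1) * (c - mx) ** 2).sum()
        cov[1, 1] = (p.sum(axis=0) * (c - my) ** 2).sum()
        cov[0, 1] = cov[1, 0] = (p * np.outer(c - mx, c - my)).sum()
        evals = np.linalg.eigvalsh(cov)
        ratio = np.sqrt(evals[1] / evals[0])
        assert ratio == pytest.approx(np.sqrt((1 + rho) / (1 - rho)), rel=0.05)

    def test_bin_halving_stability(self, gaussian_pmf):
        samples, fes = gaussian_pmf
        fine = histogram_fes(samples, default_rise_edges(width=0.0025))
        # compare on coarse centers: interpolate fine onto coarse
        c = fes.centers[0]
        cf = fine.centers[0]
        sel = np.isfinite(fes.G) & (np.abs(c - 8.3) < 0.1)
        gi = np.interp(c[sel], cf[np.isfinite(fine.G)],
                       fine.G[np.isfinite(fine.G)])
        err = np.nanmean(fes.G_err[sel])
        assert np.mean(np.abs(gi - fes.G[sel])) < max(3 * err, 0.1)


class TestMinimaAndShifts:
    def test_exact_parabola_vertex(self):
        edges = np.linspace(8.0, 8.6, 61)
        c = (edges[:-1] + edges[1:]) / 2
        vertex = 8.3123
        fes = FreeEnergySurface(edges=[edges], G=200 * (c - vertex) ** 2)
        assert locate_minimum(fes)[0] == pytest.approx(vertex, abs=1e-6)

    def test_tie_break_and_multimodal_flag(self):
        edges = np.linspace(0, 5, 6)
        G = np.array([1.0, 0.0, 1.0, 0.0, 1.0])
        fes = FreeEnergySurface(edges=[edges], G=G)
        pos, info = locate_minimum(fes, return_info=True)
        assert info["multimodal"]
        assert pos[0] == pytest.approx(1.5)  # lowest-coordinate minimum

    def test_boundary_minimum_warns(self):
        edges = np.linspace(0, 3, 4)
        fes = FreeEnergySurface(edges=[edges], G=np.array([0.0, 1.0, 2.0]))
        with pytest.warns(UserWarning, match="boundary"):
            locate_minimum(fes)

    def test_identical_surfaces_zero_shift(self, gaussian_pmf):
        _, fes = gaussian_pmf
        shift, _ = compaction_shift(fes, fes)
        assert shift == 0.0

    def test_synthetic_compaction_shift(self, gtp_traj, gdp_traj):
        edges = default_rise_edges()
        fa = histogram_fes(gtp_traj.rise[:, 0], edges)
        fb = histogram_fes(gdp_traj.rise[:, 0], edges)
        shift, sd = compaction_shift(fa, fb,
                                     samples_a=gtp_traj.rise[:, 0],
                                     samples_b=gdp_traj.rise[:, 0],
                                     n_bootstrap=20, seed=2)
        assert shift == pytest.approx(0.25, abs=0.005)  # one bin width
        assert sd > 0

    def test_marginalize_reduces_2d(self):
        rng = np.random.default_rng(11)
        xy = rng.multivariate_normal([8.2, 8.4], np.diag([0.002, 0.002]),
                                     100_000)
        edges = default_rise_edges()
        fes2 = histogram_fes(xy, [edges, edges])
        m0 = marginalize(fes2, 0)
        m1 = marginalize(fes2, 1)
        # broad wells: argmin wanders ~1 bin under sampling noise
        assert locate_minimum(m0)[0] == pytest.approx(8.2, abs=0.01)
        assert locate_minimum(m1)[0] == pytest.approx(8.4, abs=0.01)


class TestDgBetween:
    def test_same_point_zero(self, gaussian_pmf):
        _, fes = gaussian_pmf
        dg, _ = dg_between(fes, [8.3], [8.3])
        assert dg == 0.0

    def test_harmonic_displacement_cost(self, gaussian_pmf):
        # harmonic PMF: dG = 1/2 k delta^2 with k = 1/s^2
        _, fes = gaussian_pmf
        pos = locate_minimum(fes)
        delta = 0.05
        dg, err = dg_between(fes, pos, pos + delta)
        assert dg == pytest.approx(0.5 * (1 / 0.05**2) * delta**2, rel=0.1)
        assert err > 0

    def test_unsampled_query_raises(self, gaussian_pmf):
        _, fes = gaussian_pmf
        with pytest.raises(CoverageError):
            dg_between(fes, [8.3], [8.69])
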