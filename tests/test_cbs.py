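"""Born-series solver: operator maps, iteration, convergence, boundaries."""

import warnings

import numpy as np
import pytest

from pacbs import (
    AcousticMedium,
    CBSConfig,
    CBSWorkspace,
    ConvergenceWarning,
    Disk,
    OpticalThermalParams,
    SimGrid,
    abl_window,
    attenuation_coefficient,
    build_workspace,
    cbs_step,
    greens_ft,
    initial_field,
    load_field,
    potential_map,
    save_field,
    solve_cbs,
    solve_tbs,
    source_map,
    total_error,
)
from tests.conftest import medium_for


class TestOperatorMaps:
    def test_source_map_empty_scene_is_zero(self, optical):
        S = source_map(SimGrid(n=64, h_um=0.1), [], optical, 183.0)
        assert not S.any()

    def test_source_map_interior_value(self, optical, test_grid, rbc_disk):
        """Unit optical parameters at 183 MHz give -i*omega inside."""
        S = source_map(test_grid, [rbc_disk], optical, 183.0)
        inside = S[S != 0]
        assert inside.size > 0
        assert np.unique(inside) == pytest.approx(-1j * 2 * np.pi * 183e6)

    def test_source_map_pixel_count_matches_disk_area(self, optical, test_grid, rbc_disk):
        """Rasterized pixel count tracks pi*a^2/h^2 = 2375.8 within the
        lattice-circle error bound."""
        S = source_map(test_grid, [rbc_disk], optical, 183.0)
        count = int(np.count_nonzero(S))
        assert abs(count - np.pi * 2.75**2 / 0.1**2) < 60

    def test_potential_map_zero_contrast_is_uniform(self, test_grid, rbc_disk):
        medium = medium_for(1500.0)
        kf = float(medium.kf(183.0))
        eps = 0.8 * kf * kf
        V = potential_map(test_grid, [rbc_disk], medium, 183.0, eps)
        assert np.unique(V) == pytest.approx(-1j * eps)

    def test_potential_map_interior_contrast(self, test_grid, rbc_disk):
        """vs=1200 in a 1500 m/s ambient: Re(V) inside is 0.5625 kf^2."""
        medium = medium_for(1200.0)
        kf = float(medium.kf(183.0))
        eps = 0.8 * kf * kf
        V = potential_map(test_grid, [rbc_disk], medium, 183.0, eps)
        interior = V[V.real != 0]
        assert interior.real == pytest.approx(0.5625 * kf * kf, rel=1e-12)

    @pytest.mark.parametrize("vs", [1200.0, 1950.0])
    def test_default_epsilon_satisfies_guarantee(self, test_grid, rbc_disk, vs):
        """eps = 0.8 kf^2 covers both band-edge contrasts."""
        medium = medium_for(vs)
        kf = float(medium.kf(183.0))
        potential_map(test_grid, [rbc_disk], medium, 183.0, 0.8 * kf * kf)

    def test_epsilon_guarantee_violation_raises(self, test_grid, rbc_disk):
        medium = medium_for(1100.0)  # |c_hat^-2 - 1| = 0.86 > 0.8
        kf = float(medium.kf(183.0))
        with pytest.raises(ValueError, match="guarantee"):
            potential_map(test_grid, [rbc_disk], medium, 183.0, 0.8 * kf * kf)

    def test_greens_ft_reference_points(self):
        grid = SimGrid(n=64, h_um=0.1)
        kf, eps = 5e5, 2e11
        g = greens_ft(grid, kf, eps)
        assert g[0, 0] == pytest.approx(-1.0 / (kf * kf + 1j * eps))
        # magnitude is bounded by 1/eps, attained on the resonant shell
        assert np.abs(g).max() <= 1.0 / eps * (1 + 1e-12)
        p = grid.fourier_coords()
        kf_exact = abs(p[5])  # lattice point with |p| = kf exactly
        g2 = greens_ft(grid, kf_exact, eps)
        assert np.abs(g2).max() == pytest.approx(1.0 / eps)
        assert g2[5, 0] == pytest.approx(1j / eps)


class TestABLWindow:
    def test_sigmoid_midpoint_and_edge(self):
        """Profile is 0.5 half-way into the frame and ~2.2e-7 at the outer
        boundary for the reference steepness (kappa = 6136 Np/cm over a
        50 um frame)."""
        grid = SimGrid(n=2048, h_um=0.1)
        w = abl_window(grid, 500, 6136.0)
        prof = w[:, 1024]
        assert prof[250] == pytest.approx(0.5, rel=1e-9)  # x = 0.5*d*h
        assert prof[0] == pytest.approx(2.179e-7, rel=1e-3)  # x = 0

    def test_interior_is_exactly_one(self):
        grid = SimGrid(n=256, h_um=0.1)
        w = abl_window(grid, 64, 6136.0)
        assert (w[64:-64, 64:-64] == 1.0).all()
        assert (w[:64, :] < 1.0).all()

    def test_rejects_frame_wider_than_half_grid(self):
        with pytest.raises(ValueError):
            abl_window(SimGrid(n=64, h_um=0.1), 32, 6136.0)


def _manual_workspace(n, kf, eps, S, V):
    grid = SimGrid(n=n, h_um=0.1)
    return CBSWorkspace(
        grid=grid,
        f_mhz=0.0,
        epsilon=eps,
        kf=kf,
        S_map=S,
        V_map=V,
        greens_ft=greens_ft(grid, kf, eps),
        gamma_map=(1j / eps) * V,
        abl_window=np.ones((n, n)),
    )


class TestIteration:
    def test_initial_field_zero_source(self):
        n, kf = 64, 5e5
        eps = 0.8 * kf * kf
        ws = _manual_workspace(
            n, kf, eps,
            np.zeros((n, n), complex),
            np.full((n, n), -1j * eps, complex),
        )
        assert not initial_field(ws).any()

    def test_initial_field_constant_source(self):
        """A spatially constant source excites only the zero-frequency bin:
        psi0 = gamma * s0 * g(0)."""
        n, kf = 64, 5e5
        eps = 0.8 * kf * kf
        s0 = 3.0 - 2.0j
        V = np.full((n, n), -1j * eps, complex)
        ws = _manual_workspace(n, kf, eps, np.full((n, n), s0, complex), V)
        psi0 = initial_field(ws)
        expected = (1j / eps) * (-1j * eps) * s0 * ws.greens_ft[0, 0]
        assert psi0 == pytest.approx(np.full((n, n), expected))

    def test_initial_field_decays_from_point_source(self):
        """|psi0| of a single-pixel source decays with distance, consistent
        with the damped Green's function."""
        n, kf = 64, 5e5
        eps = 0.8 * kf * kf
        S = np.zeros((n, n), complex)
        S[n // 2, n // 2] = 1.0
        ws = _manual_workspace(n, kf, eps, S, np.full((n, n), -1j * eps, complex))
        prof = np.abs(initial_field(ws)[n // 2, n // 2 :])
        assert prof[0] > prof[4] > prof[8] > prof[16]

    def test_cbs_step_zero_fixed_point(self, optical):
        grid = SimGrid(n=64, h_um=0.1)
        ws = build_workspace(
            grid, [], medium_for(1500.0), optical, 183.0, CBSConfig(abl_thickness=16)
        )
        assert not cbs_step(np.zeros((64, 64), complex), ws).any()

    def test_cbs_step_matches_direct_dft_oracle(self, optical):
        """On a 32x32 lattice one preconditioned update equals an
        independently coded dense-DFT evaluation to 1e-12 relative."""
        n = 32
        grid = SimGrid(n=n, h_um=0.1)
        medium = medium_for(1950.0)
        cfg = CBSConfig(abl_thickness=8)
        ws = build_workspace(grid, [Disk(radius=0.5)], medium, optical, 400.0, cfg)
        rng = np.random.default_rng(3)
        psi = rng.standard_normal((n, n)) + 1j * rng.standard_normal((n, n))
        psi *= 1e-3
        got = cbs_step(psi, ws)
        # oracle: explicit DFT matrices, no FFT library on the checked path
        k = np.arange(n)
        F = np.exp(-2j * np.pi * np.outer(k, k) / n)
        Finv = np.conj(F) / n
        work = ws.V_map * psi + ws.S_map
        work_ft = F @ work @ F.T
        conv = Finv @ (ws.greens_ft * work_ft) @ Finv.T
        expected = ws.abl_window * (psi - ws.gamma_map * (psi - conv))
        assert np.linalg.norm(got - expected) / np.linalg.norm(expected) < 1e-12

    def test_total_error_reference_values(self):
        grid = SimGrid(n=64, h_um=0.1)
        c = grid.center_row
        old = np.zeros((64, 64), complex)
        old[c, 0], old[c, 1] = 1.0, 1j
        new = old.copy()
        assert total_error(new, old, grid) == 0.0
        assert total_error(2 * old, old, grid) == pytest.approx(1.0)
        new[c, 0] = 1.0 + 1e-4
        assert total_error(new, old, grid) == pytest.approx(5e-5)

    def test_total_error_rejects_zero_reference(self):
        grid = SimGrid(n=64, h_um=0.1)
        z = np.zeros((64, 64), complex)
        with pytest.raises(ZeroDivisionError):
            total_error(z, z, grid)


class TestSolvers:
    def test_cbs_converges_and_error_trace_is_consistent(
        self, test_grid, test_config, optical, rbc_disk
    ):
        sol = solve_cbs([rbc_disk], medium_for(1950.0), optical, 183.0,
                        test_grid, test_config)
        assert sol.converged
        assert sol.iterations == len(sol.error_trace)
        assert sol.error_trace[-1] < test_config.error_threshold
        assert np.all(np.isfinite(sol.psi))
        # one further step stays below threshold at the fixed point
        ws = build_workspace(test_grid, [rbc_disk], medium_for(1950.0),
                             optical, 183.0, test_config)
        again = cbs_step(sol.psi, ws)
        assert total_error(again, sol.psi, test_grid) < test_config.error_threshold

    def test_abl_suppresses_boundary_field(self, test_grid, test_config,
                                           optical, rbc_disk):
        """Outermost pixel ring is damped to <= 1e-3 of the interior peak,
        preventing periodic wrap-around."""
        sol = solve_cbs([rbc_disk], medium_for(1950.0), optical, 366.0,
                        test_grid, test_config)
        edge = np.concatenate(
            [np.abs(sol.psi[0, :]), np.abs(sol.psi[-1, :]),
             np.abs(sol.psi[:, 0]), np.abs(sol.psi[:, -1])]
        )
        d = test_config.abl_thickness
        interior_max = np.abs(sol.psi[d:-d, d:-d]).max()
        assert edge.max() <= 1e-3 * interior_max

    def test_iterations_grow_with_frequency(self, test_grid, test_config,
                                            optical, rbc_disk):
        medium = medium_for(1950.0)
        iters = [
            solve_cbs([rbc_disk], medium, optical, f, test_grid, test_config).iterations
            for f in (183.0, 366.0, 732.0)
        ]
        assert iters[0] <= iters[1] <= iters[2]

    def test_solve_is_deterministic(self, test_config, optical, rbc_disk):
        grid = SimGrid(n=256, h_um=0.1)
        cfg = CBSConfig(abl_thickness=64)
        a = solve_cbs([rbc_disk], medium_for(1200.0), optical, 183.0, grid, cfg)
        b = solve_cbs([rbc_disk], medium_for(1200.0), optical, 183.0, grid, cfg)
        assert np.array_equal(a.psi, b.psi)
        assert a.iterations == b.iterations

    def test_nonconvergence_warns_but_returns(self, optical, rbc_disk):
        grid = SimGrid(n=256, h_um=0.1)
        cfg = CBSConfig(abl_thickness=64, max_iter=3)
        with pytest.warns(ConvergenceWarning):
            sol = solve_cbs([rbc_disk], medium_for(1950.0), optical, 732.0, grid, cfg)
        assert not sol.converged
        assert sol.iterations == 3

    def test_tbs_agrees_with_cbs_for_weak_scattering(self, optical):
        """Zero contrast, small disk, low frequency: both series approximate
        the same solution (<= 1% on the center line)."""
        grid = SimGrid(n=256, h_um=0.1)
        cfg = CBSConfig(abl_thickness=64)
        medium = medium_for(1500.0)
        tbs = solve_tbs([Disk(radius=1.0)], medium, optical, 50.0, grid, cfg)
        cbs = solve_cbs([Disk(radius=1.0)], medium, optical, 50.0, grid, cfg)
        assert tbs.converged
        c = grid.center_row
        rel = np.linalg.norm(tbs.psi[c] - cbs.psi[c]) / np.linalg.norm(cbs.psi[c])
        assert rel <= 0.01

    def test_tbs_diverges_for_strong_scattering(self, optical, rbc_disk):
        """Large contrast at the band's top frequency: the unpreconditioned
        series fails and is flagged."""
        grid = SimGrid(n=256, h_um=0.1)
        cfg = CBSConfig(abl_thickness=64, max_iter=300)
        with pytest.warns(ConvergenceWarning):
            sol = solve_tbs([rbc_disk], medium_for(1950.0), optical, 2197.0, grid, cfg)
        assert not sol.converged

    def test_tbs_zero_source_converges_immediately(self, optical):
        grid = SimGrid(n=256, h_um=0.1)
        cfg = CBSConfig(abl_thickness=64)
        sol = solve_tbs([], medium_for(1950.0), optical, 183.0, grid, cfg)
        assert sol.converged
        assert sol.iterations == 1
        assert not sol.psi.any()


class TestAttenuation:
    def test_linear_in_frequency_for_default_rule(self):
        """With eps = 0.8 kf^2 the implied attenuation is 0.4 kf."""
        kf = 1.234e6
        assert attenuation_coefficient(0.8 * kf * kf, kf) == pytest.approx(0.4 * kf)
        assert attenuation_coefficient(0.0, kf) == 0.0


class TestFieldIO:
    def test_hdf5_round_trip(self, tmp_path, optical, rbc_disk):
        grid = SimGrid(n=64, h_um=0.1)
        cfg = CBSConfig(abl_thickness=16, max_iter=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            sol = solve_cbs([Disk(radius=0.5)], medium_for(1500.0), optical,
                            100.0, grid, cfg)
        path = tmp_path / "field.h5"
        save_field(sol, path, config_hash="abc123")
        back = load_field(path)
        assert np.array_equal(back.psi, sol.psi)
        assert back.iterations == sol.iterations
        assert back.grid.n == 64
        assert back.medium.vs == 1500.0
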