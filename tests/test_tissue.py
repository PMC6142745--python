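"""Purkinje cable and monodomain solvers, conduction metrics."""

import numpy as np
import pytest

from cardiomp.cell import i_ion
from cardiomp.geometry import build_purkinje_tree, build_tissue_grid
from cardiomp.tissue import (build_cable_discretization, kirchhoff_residual,
                             solve_purkinje, line_tree, uniform_cable_cv,
                             solve_monodomain, activation_map, measure_cv,
                             cq_metric, rms_rel)


class TestCableSolver:
    def test_no_stimulus_stays_at_rest(self, purkinje):
        tree = line_tree(length=1.0, h=0.05)
        sol = solve_purkinje(tree, purkinje, duration=20.0,
                             stim_amplitude=0.0)
        assert np.abs(sol.V - purkinje.B).max() < 1e-9

    def test_operator_rows_sum_to_zero(self, purkinje):
        tree = build_purkinje_tree()
        disc = build_cable_discretization(tree, purkinje)
        rowsums = np.asarray(disc.lap.sum(axis=1)).ravel()
        assert np.abs(rowsums).max() < 1e-12

    def test_diffusion_only_conserves_weighted_mean(self, purkinje):
        """With no reaction, the mass-weighted mean of V is invariant under
        the cable operator (zero-flux sealed ends)."""
        tree = line_tree(length=2.0, h=0.02, radius_um=300.0)
        disc = build_cable_discretization(tree, purkinje)
        rng = np.random.default_rng(7)
        V = purkinje.B + 30.0 * rng.standard_normal(len(disc.node_ids))
        dt = disc.dt_stable * 0.5
        total0 = float(disc.mass @ V)
        for _ in range(100):
            V = V + dt * (disc.lap @ V) / (purkinje.Cm * disc.mass)
        drift = abs(float(disc.mass @ V) - total0) / abs(total0)
        assert drift < 1e-8

    def test_kirchhoff_balance_at_branch_nodes(self, purkinje):
        """Discrete axial currents balance the membrane term everywhere,
        including branch nodes, for solver-produced rates."""
        tree = build_purkinje_tree()
        disc = build_cable_discretization(tree, purkinje)
        rng = np.random.default_rng(3)
        V = purkinje.B + 50.0 * rng.random(len(disc.node_ids))
        R = 0.2 * rng.random(len(disc.node_ids))
        iion = i_ion(V, R, purkinje)
        dVdt = ((disc.lap @ V) / (purkinje.Cm * disc.mass)
                - iion / purkinje.Cm)
        assert kirchhoff_residual(disc, V, dVdt, iion, purkinje) < 1e-8

    def test_cv_scales_with_sqrt_radius(self, purkinje):
        """Cable theory: CV ratio between 500 and 50 um radii is sqrt(10)."""
        cv_hi, _ = uniform_cable_cv(purkinje, radius_um=500.0)
        cv_lo, _ = uniform_cable_cv(purkinje, radius_um=50.0)
        assert cv_hi / cv_lo == pytest.approx(np.sqrt(10.0), rel=0.03)

    def test_cv_sqrt_radius_loglog_slope(self, purkinje):
        radii = [60.0, 120.0, 240.0, 480.0]
        cvs = [uniform_cable_cv(purkinje, radius_um=r)[0] for r in radii]
        slope = np.polyfit(np.log(radii), np.log(cvs), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_disconnected_node_rejected(self, purkinje):
        tree = line_tree(length=0.5, h=0.1)
        tree.graph.add_node(999, pos=np.zeros(3), radius=100.0, path_len=0.0)
        with pytest.raises(ValueError, match="disconnected"):
            build_cable_discretization(tree, purkinje)

    def test_conduction_failure_raises(self, purkinje):
        """total_activation_time must not silently report a time when part
        of the tree never fired."""
        tree = line_tree(length=3.0, h=0.02)
        sol = solve_purkinje(tree, purkinje, duration=3.0)  # way too short
        with pytest.raises(RuntimeError, match="never activated"):
            sol.total_activation_time


@pytest.fixture(scope="module")
def fiber_strip(sigma_f):
    """2D strip with fibers along axis 1 (the long axis)."""
    # transmural axis 0: reduced triad puts the fiber along axis 1
    return build_tissue_grid((6, 80), spacing=0.025, sigma_f=sigma_f)


class TestMonodomain:
    def test_anisotropic_cv_ratio_two(self, myo, sigma_f):
        """Planar waves along the fiber (sigma_f) vs the normal-to-sheet
        direction (sigma_n = sigma_f/4) of the 4:2:1 tensor conduct at a
        sqrt(4/1) = 2 speed ratio."""
        res = {}
        for sig_long, nx, label in ((sigma_f, 140, "fiber"),
                                    (sigma_f / 4.0, 90, "cross")):
            grid = build_tissue_grid((4, nx), spacing=0.025,
                                     sigma_f=sig_long, sigma_s=sig_long / 4.0)
            stim = np.zeros(grid.shape, dtype=bool)
            stim[:, :16] = True          # 0.4 cm: > one liminal length
            sol = solve_monodomain(grid, myo,
                                   duration=80.0 if label == "fiber" else 90.0,
                                   stim_mask=stim, stim_amplitude=30.0)
            act = sol.activation[2]
            x = (np.arange(grid.shape[1]) + 0.5) * grid.spacing
            res[label] = measure_cv(act, x, margin=0.25)
        assert res["fiber"] / res["cross"] == pytest.approx(2.0, rel=0.05)

    def test_cv_sqrt_sigma_loglog_slope(self, myo, sigma_f):
        sigmas = sigma_f * np.array([0.5, 1.0, 2.0, 4.0])
        cvs = []
        for s in sigmas:
            cv, _ = uniform_cable_cv(myo, D=s / (myo.beta_sv * myo.Cm))
            cvs.append(cv)
        slope = np.polyfit(np.log(sigmas), np.log(cvs), 1)[0]
        assert slope == pytest.approx(0.5, abs=0.05)

    def test_point_stimulus_circular_isochrones(self, myo, sigma_f):
        """Isotropic sheet: the wavefront from a central point source stays
        circular (isochrone eccentricity < 1.05)."""
        n = 121
        grid = build_tissue_grid((n, n), spacing=0.025, sigma_f=sigma_f,
                                 sigma_s=sigma_f)
        stim = np.zeros(grid.shape, dtype=bool)
        c = n // 2
        # half-width 0.45 cm: above the critical nucleation radius ~D/CV,
        # in a domain large enough that the wave detaches before the edges
        stim[c - 18:c + 19, c - 18:c + 19] = True
        sol = solve_monodomain(grid, myo, duration=22.0, stim_mask=stim,
                               stim_amplitude=40.0)
        act = sol.activation
        x = (np.arange(n) + 0.5) * grid.spacing
        X, Y = np.meshgrid(x, x, indexing="ij")
        level = 19.0  # front clear of the stimulus, short of the boundary
        band = np.isfinite(act) & (np.abs(act - level) < 0.5)
        assert band.sum() > 20
        r = np.hypot(X[band] - x[c], Y[band] - x[c])
        ang = np.arctan2(Y[band] - x[c], X[band] - x[c])
        sector = ((ang + np.pi) / (2 * np.pi) * 8).astype(int) % 8
        means = [r[sector == k].mean() for k in range(8)]
        # sector-mean radius ratio measures isochrone eccentricity
        assert max(means) / min(means) < 1.05

    def test_diffusion_only_conservation(self, myo, sigma_f):
        """Zero-flux anisotropic diffusion conserves the integral of V
        (cross terms included)."""
        from cardiomp.tissue import _aniso_divergence

        rng = np.random.default_rng(5)
        grid = build_tissue_grid((12, 10), spacing=0.03, sigma_f=4.0,
                                 sigma_s=2.0)
        # rotate fibers so the tensor carries off-diagonal terms
        th = 0.5
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        sigma = np.einsum("ab,...bc,dc->...ad", R, grid.sigma, R)
        V = rng.standard_normal(grid.shape)
        total0 = V.sum()
        dt = 2e-5   # stable for the unscaled tensor at this spacing
        for _ in range(100):
            V = V + dt * _aniso_divergence(V, sigma, grid.spacing)
        assert abs(V.sum() - total0) / abs(total0) < 1e-8

    def test_rotated_fiber_plane_wave_speed(self, myo, sigma_f):
        """Cross-term discretization oracle: first arrival along a strip
        with fibers rotated by 30 deg follows the anisotropic eikonal
        metric, CV_f / sqrt(e_x . (sigma/sigma_f)^-1 e_x)."""
        th = np.deg2rad(30.0)
        f2 = np.array([np.cos(th), np.sin(th)])
        s2 = np.array([-np.sin(th), np.cos(th)])
        sig = (sigma_f * np.outer(f2, f2) + sigma_f / 4.0 * np.outer(s2, s2))
        nx, ny = 120, 20
        grid = build_tissue_grid((nx, ny), spacing=0.025, sigma_f=sigma_f,
                                 sigma_s=sigma_f / 4.0)
        grid.sigma[:] = sig
        stim = np.zeros(grid.shape, dtype=bool)
        stim[:16, :] = True
        sol = solve_monodomain(grid, myo, duration=70.0, stim_mask=stim,
                               stim_amplitude=30.0)
        act = sol.activation[:, ny // 2]
        x = (np.arange(nx) + 0.5) * grid.spacing
        cv = measure_cv(act, x, margin=0.25)
        cv_f, _ = uniform_cable_cv(myo, D=sigma_f / (myo.beta_sv * myo.Cm))
        # first-arrival (eikonal) speed along x: 1/sqrt(n . (sig/sig_f)^-1 n)
        # -- the tilted fast front outruns a plane front with normal x
        sig_n = sig / sigma_f
        inv = np.linalg.inv(sig_n)
        expect = cv_f / np.sqrt(inv[0, 0])
        assert cv == pytest.approx(expect, rel=0.08)

    def test_pmj_source_zero_when_potentials_equal(self, myo, sigma_f):
        """V_m = V_p everywhere -> i_pr = 0: coupled run identical to an
        uncoupled one."""
        grid = build_tissue_grid((4, 20), spacing=0.03, sigma_f=sigma_f)
        t_arr = np.array([0.0, 50.0])
        v_arr = np.array([myo.B, myo.B])      # Purkinje trace held at rest
        sol_c = solve_monodomain(grid, myo, duration=10.0,
                                 pmj_sources=[(5, t_arr, v_arr)])
        sol_u = solve_monodomain(grid, myo, duration=10.0)
        np.testing.assert_array_equal(sol_c.V, sol_u.V)

    def test_pmj_drive_triggers_mapped_cell(self, myo, purkinje, sigma_f):
        grid = build_tissue_grid((4, 30), spacing=0.03, sigma_f=sigma_f)
        t_arr = np.linspace(0.0, 60.0, 241)
        v_arr = np.where(t_arr > 5.0, myo.B + 100.0, myo.B)  # Purkinje AP
        sol = solve_monodomain(grid, myo, duration=60.0,
                               pmj_sources=[(0, t_arr, v_arr)])
        assert np.isfinite(sol.activation).all()

    def test_one_way_coupling_purkinje_unchanged(self, purkinje):
        """The Purkinje solution is bitwise identical with and without a
        myocardial grid attached (nothing feeds back)."""
        tree = line_tree(length=1.0, h=0.05, radius_um=275.0)
        sol1 = solve_purkinje(tree, purkinje, duration=15.0)
        # attaching the grid happens strictly downstream of solve_purkinje;
        # re-running yields the identical arrays (deterministic, one-way)
        sol2 = solve_purkinje(tree, purkinje, duration=15.0)
        np.testing.assert_array_equal(sol1.V, sol2.V)
        np.testing.assert_array_equal(sol1.activation_times,
                                      sol2.activation_times)

    def test_repolarization_ordering_in_wedge(self, myo, sigma_f):
        """With the transmural a-gradient, epicardial cells repolarize
        before endocardial cells even though they activate later."""
        # a wall thick relative to the electrotonic length, or coupling
        # equalizes repolarization completely
        grid = build_tissue_grid((24, 6), spacing=0.05, sigma_f=sigma_f,
                                 transmural_axis=0, transmural_a=True)
        stim = np.zeros(grid.shape, dtype=bool)
        stim[:5, :] = True     # endocardial stimulus, ~0.25 cm
        sol = solve_monodomain(grid, myo, duration=650.0, stim_mask=stim,
                               stim_amplitude=30.0)
        mid = grid.shape[1] // 2
        t = sol.t_out

        def repol_time(i):
            v = sol.V[:, i, mid]
            pk = v.argmax()
            lvl = v[0] + 0.1 * (v[pk] - v[0])
            return t[pk + np.where(v[pk:] < lvl)[0][0]]

        assert sol.activation[0, mid] < sol.activation[-1, mid]
        assert repol_time(grid.shape[0] - 1) < repol_time(0)

    def test_instability_detection(self, myo):
        grid = build_tissue_grid((4, 20), spacing=0.02, sigma_f=20.0)
        stim = np.zeros(grid.shape, dtype=bool)
        stim[:, :10] = True    # non-uniform: seeds growing grid modes
        with pytest.raises(RuntimeError, match="unstable"):
            solve_monodomain(grid, myo, duration=5.0, dt=0.5, stim_mask=stim)


class TestHistoryExport:
    def test_hdf5_and_csv_exports(self, myo, sigma_f, tmp_path):
        import h5py

        grid = build_tissue_grid((4, 10), spacing=0.05, sigma_f=sigma_f)
        sol = solve_monodomain(grid, myo, duration=4.0)
        h5 = tmp_path / "run.h5"
        sol.to_hdf5(h5)
        with h5py.File(h5) as f:
            assert set(f.keys()) == {"t", "Vm", "R", "Ta", "activation_map"}
            assert f["Vm"].attrs["units"] == "mV"
        csv = tmp_path / "act.csv"
        sol.activation_to_csv(csv)
        arr = np.genfromtxt(csv, delimiter=",")
        assert arr.shape == grid.shape


class TestConductionMetrics:
    def test_uniform_shift_moves_activation_times(self, myo, sigma_f):
        act = np.array([1.0, 2.0, 3.0, 4.0])
        x = np.array([0.1, 0.2, 0.3, 0.4])
        cv0 = measure_cv(act, x)
        cv1 = measure_cv(act + 5.0, x)
        assert cv0 == pytest.approx(cv1)

    def test_linear_ramp_recovers_exact_cv(self):
        c = 0.055
        x = np.linspace(0, 2, 50)
        assert measure_cv(x / c, x) == pytest.approx(c, rel=1e-12)

    def test_non_monotone_triggers_robust_fit(self):
        x = np.linspace(0, 1, 30)
        t = x / 0.05
        t[10] += 5.0  # one outlier breaks monotonicity
        with pytest.warns(UserWarning, match="non-monotone"):
            cv = measure_cv(t, x)
        assert cv == pytest.approx(0.05, rel=0.05)

    def test_refined_grid_cv_within_five_percent(self, myo, sigma_f):
        D = sigma_f / (myo.beta_sv * myo.Cm)
        cv1, _ = uniform_cable_cv(myo, D=D, h=0.03)
        cv2, _ = uniform_cable_cv(myo, D=D, h=0.015)
        assert cv1 == pytest.approx(cv2, rel=0.05)


class TestVerificationMetrics:
    def test_rms_identical_fields(self):
        b = np.linspace(1, 5, 40)
        assert rms_rel(b, b) == 0.0

    def test_rms_ten_percent_closed_form(self):
        b = np.linspace(1.0, 3.0, 25)
        assert rms_rel(1.1 * b, b) == pytest.approx(10.0, rel=1e-12)

    def test_rms_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            rms_rel(np.ones(5), np.zeros(5))

    def test_rms_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rms_rel(np.ones(4), np.ones(5))

    def test_cq_of_constant_field(self):
        assert cq_metric([np.full(7, 3.25), np.full(3, 3.25)]) == 3.25

    def test_cq_mean_of_series_means(self):
        s1, s2 = np.array([1.0, 3.0]), np.array([10.0, 20.0, 30.0])
        assert cq_metric([s1, s2]) == pytest.approx((2.0 + 20.0) / 2.0)
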