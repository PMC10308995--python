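"""Brownian-motion Monte Carlo loading model: Stokes–Einstein helpers,
capture simulation invariants, and step-scale calibration."""

import math

import numpy as np
import pytest
import sympy

from optopore import (CellModel, MoleculeSpec, PoreSpec, SimParams,
                      calibrate_step, delivery_time_course,
                      diffusion_coefficient, free_walk, loading_vs_mw,
                      loading_vs_time, molecule_radius, random_pores,
                      simulate_loading, step_scale)
from optopore.mc import KB


class TestPhysicalHelpers:
    def test_radius_cube_root_scaling(self):
        r1 = molecule_radius(1.0, 1e-3)
        assert molecule_radius(8.0, 1e-3) / r1 == pytest.approx(2.0,
                                                                rel=1e-12)
        for m, mp in [(5.0, 40.0), (10.0, 70.0), (3.3, 100.0)]:
            ratio = molecule_radius(m, 1e-3) / molecule_radius(mp, 1e-3)
            assert ratio == pytest.approx((m / mp) ** (1 / 3), rel=1e-12)

    def test_radius_matches_high_precision_formula(self):
        """R = (3*eta*M / (10*pi*N))**(1/3) against a 50-digit evaluation."""
        eta, m, n_av = sympy.Float("1.0e-3", 50), sympy.Integer(10), \
            sympy.Float("6.02214076e23", 50)
        expected = float(sympy.real_root(
            3 * eta * m / (10 * sympy.pi * n_av), 3).evalf(50))
        assert molecule_radius(10.0, 1.0e-3) == pytest.approx(expected,
                                                              rel=1e-12)

    def test_diffusion_coefficient_proportionalities(self):
        d = diffusion_coefficient(310.0, 1e-3, 1e-9)
        assert diffusion_coefficient(310.0, 1e-3, 0.5e-9) == pytest.approx(
            2 * d, rel=1e-12)
        assert diffusion_coefficient(620.0, 1e-3, 1e-9) == pytest.approx(
            2 * d, rel=1e-12)

    def test_diffusion_coefficient_matches_high_precision_formula(self):
        kb, t = sympy.Float(repr(KB), 50), sympy.Integer(310)
        eta, r = sympy.Float("1.0e-3", 50), sympy.Float("1.0e-9", 50)
        expected = float((kb * t / (6 * sympy.pi * eta * r)).evalf(50))
        assert diffusion_coefficient(310.0, 1e-3, 1e-9) == pytest.approx(
            expected, rel=1e-12)

    def test_step_scale_identity_and_exact_ratios(self):
        assert step_scale(10.0, 10.0, 0.3) == 0.3
        assert step_scale(5.0, 10.0, 1.0) / step_scale(40.0, 10.0, 1.0) \
            == pytest.approx(2.0, rel=1e-12)
        expected = float(sympy.real_root(sympy.Integer(10), 3).evalf(50))
        assert step_scale(10.0, 100.0, 1.0) == pytest.approx(expected,
                                                             rel=1e-12)

    @pytest.mark.parametrize("fn,args", [
        (molecule_radius, (0.0, 1e-3)),
        (molecule_radius, (10.0, -1e-3)),
        (diffusion_coefficient, (0.0, 1e-3, 1e-9)),
        (diffusion_coefficient, (310.0, 1e-3, 0.0)),
        (step_scale, (-5.0, 10.0, 1.0)),
    ])
    def test_nonpositive_inputs_rejected(self, fn, args):
        with pytest.raises(ValueError):
            fn(*args)


class TestGeometryTypes:
    def test_pore_requires_unit_direction(self):
        with pytest.raises(ValueError, match="unit"):
            PoreSpec((0.0, 0.0, 2.0), 0.2)

    def test_pore_half_angle_range(self):
        with pytest.raises(ValueError):
            PoreSpec((0.0, 0.0, 1.0), math.pi / 2)

    def test_overlapping_caps_rejected(self):
        p1 = PoreSpec((0.0, 0.0, 1.0), 0.3)
        p2 = PoreSpec(tuple(np.array([math.sin(0.4), 0, math.cos(0.4)])), 0.3)
        with pytest.raises(ValueError, match="overlap"):
            CellModel(pores=(p1, p2))

    def test_domain_must_enclose_cell(self):
        with pytest.raises(ValueError):
            CellModel(cell_radius=2.0, domain_radius=1.5)

    def test_random_pores_disjoint(self):
        pores = random_pores(12, 0.3, seed=3)
        cell = CellModel(pores=tuple(pores), domain_radius=3.0)
        assert len(cell.pores) == 12


class TestSimulateLoading:
    def test_zero_open_time_gives_exactly_zero(self, small_cell):
        res = simulate_loading(small_cell, MoleculeSpec(10.0),
                               SimParams(n_particles=200, open_time=0.0,
                                         n_replicates=2, seed=1))
        assert res.loading_efficiency == 0.0
        assert res.delivered_count == 0

    def test_no_pores_gives_exactly_zero(self):
        cell = CellModel(pores=(), domain_radius=2.5)
        res = simulate_loading(cell, MoleculeSpec(10.0),
                               SimParams(n_particles=200, open_time=20.0,
                                         n_replicates=2, seed=1))
        assert res.loading_efficiency == 0.0

    def test_seeded_determinism(self, small_cell, fast_sim):
        r1 = simulate_loading(small_cell, MoleculeSpec(10.0), fast_sim)
        r2 = simulate_loading(small_cell, MoleculeSpec(10.0), fast_sim)
        assert r1.delivered_count == r2.delivered_count
        assert r1.per_replicate == r2.per_replicate

    def test_conservation_and_range(self, small_cell, fast_sim):
        res = simulate_loading(small_cell, MoleculeSpec(10.0), fast_sim)
        assert res.delivered_count + res.surviving_count == res.total_count
        assert 0.0 <= res.loading_efficiency <= 1.0
        assert 0.0 < res.loading_efficiency < 1.0  # nondegenerate run

    def test_fully_absorbing_sphere_captures_everything(self):
        """An absorbing trap in a bounded reflecting domain captures all
        walkers at long times; checked against a 100-particle dense-dt
        brute-force run (5x finer step)."""
        cell = CellModel(pores=(), domain_radius=2.5, absorb_everywhere=True)
        mol = MoleculeSpec(10.0, step_ref=0.25)
        res = simulate_loading(cell, mol,
                               SimParams(n_particles=1000, open_time=800.0,
                                         n_replicates=4, seed=2))
        assert res.loading_efficiency >= 0.99
        default_dt = 800.0 / mc_steps(cell, mol, 800.0)
        oracle = simulate_loading(
            cell, mol, SimParams(n_particles=100, open_time=800.0,
                                 dt=default_dt / 5.0, n_replicates=4, seed=2))
        assert oracle.loading_efficiency >= 0.99

    def test_loading_nondecreasing_in_open_time(self, small_cell):
        sim = SimParams(n_particles=1500, n_replicates=10, seed=3)
        mol = MoleculeSpec(10.0, step_ref=0.14)
        table = loading_vs_time([10.0, 30.0, 60.0, 100.0], mol, small_cell,
                                sim)
        assert np.all(np.diff(table.loading_mean.to_numpy()) >= 0)

    def test_loading_nonincreasing_in_mw(self, small_cell):
        sim = SimParams(n_particles=1500, n_replicates=10, seed=3)
        table = loading_vs_mw([5.0, 10.0, 40.0, 70.0, 100.0], 60.0,
                              small_cell, sim, step_ref=0.14)
        assert np.all(np.diff(table.loading_mean.to_numpy()) <= 0)

    def test_rotation_invariance_of_loading(self, one_pore_cell):
        """Rotating the pore configuration leaves the expected loading
        unchanged (statistical check over replicates)."""
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [0.7, -1.1, 0.4])
        rotated = CellModel(
            pores=tuple(PoreSpec(tuple(rot.apply(np.asarray(p.direction))),
                                 p.angular_radius)
                        for p in one_pore_cell.pores),
            domain_radius=one_pore_cell.domain_radius)
        sim = SimParams(n_particles=2000, open_time=40.0, n_replicates=8,
                        seed=5)
        mol = MoleculeSpec(10.0, step_ref=0.2)
        r1 = simulate_loading(one_pore_cell, mol, sim)
        r2 = simulate_loading(rotated, mol, sim)
        pooled = math.hypot(r1.sem_over_replicates, r2.sem_over_replicates)
        assert abs(r1.loading_efficiency - r2.loading_efficiency) < 4 * pooled

    def test_doubling_pores_does_not_decrease_loading(self, one_pore_cell):
        doubled = CellModel(
            pores=one_pore_cell.pores + (PoreSpec((0.0, 0.0, -1.0), 0.4),),
            domain_radius=one_pore_cell.domain_radius)
        sim = SimParams(n_particles=2000, open_time=40.0, n_replicates=8,
                        seed=6)
        mol = MoleculeSpec(10.0, step_ref=0.2)
        r1 = simulate_loading(one_pore_cell, mol, sim)
        r2 = simulate_loading(doubled, mol, sim)
        pooled = math.hypot(r1.sem_over_replicates, r2.sem_over_replicates)
        assert r2.loading_efficiency >= r1.loading_efficiency - 3 * pooled

    def test_msd_per_step_scales_as_mw_minus_two_thirds(self):
        """Free-walk MSD per step against molecular weight: log-log slope
        -2/3 within 0.05."""
        mws = np.array([5.0, 10.0, 40.0, 70.0, 100.0])
        msd = []
        for i, mw in enumerate(mws):
            pos = free_walk(MoleculeSpec(mw), n_particles=200, n_steps=50,
                            dt=0.5, seed=20 + i)
            steps = np.diff(pos, axis=0)
            msd.append(float(np.mean(np.sum(steps ** 2, axis=2))))
        slope = np.polyfit(np.log(mws), np.log(msd), 1)[0]
        assert slope == pytest.approx(-2.0 / 3.0, abs=0.05)

    def test_fixed_step_model_is_diffusive_alternative(self, small_cell):
        """Fixed-length isotropic steps (matched mean-square displacement)
        give loading statistically comparable to Gaussian steps."""
        mol = MoleculeSpec(10.0, step_ref=0.14)
        g = simulate_loading(small_cell, mol,
                             SimParams(n_particles=2000, open_time=40.0,
                                       n_replicates=6, seed=7))
        f = simulate_loading(small_cell, mol,
                             SimParams(n_particles=2000, open_time=40.0,
                                       n_replicates=6, seed=7,
                                       step_model="fixed"))
        assert abs(g.loading_efficiency - f.loading_efficiency) < 0.05

    def test_early_capture_grows_linearly(self, small_cell):
        """Before depletion the capture rate is steady: a linear fit over
        the first 10% of the open time has R^2 >= 0.95 (replicate mean)."""
        sim = SimParams(n_particles=2000, open_time=200.0, n_replicates=20,
                        seed=8)
        course = delivery_time_course(small_cell, MoleculeSpec(10.0,
                                                               step_ref=0.14),
                                      sim)
        early = course[course.time_s <= 20.0]
        coef = np.polyfit(early.time_s, early.cum_delivered_frac, 1)
        pred = np.polyval(coef, early.time_s)
        ss_res = np.sum((early.cum_delivered_frac - pred) ** 2)
        ss_tot = np.sum((early.cum_delivered_frac
                         - early.cum_delivered_frac.mean()) ** 2)
        assert 1 - ss_res / ss_tot >= 0.95

    def test_short_open_time_warns_and_returns_zero(self, small_cell):
        sim = SimParams(n_particles=100, open_time=0.001, dt=1.0,
                        n_replicates=2, seed=1)
        with pytest.warns(UserWarning, match="no steps"):
            res = simulate_loading(small_cell, MoleculeSpec(10.0), sim)
        assert res.loading_efficiency == 0.0

    def test_shrinking_pores_reduce_loading(self, small_cell):
        shrink = CellModel(pores=small_cell.pores,
                           domain_radius=small_cell.domain_radius,
                           shrinking_pores=True)
        mol = MoleculeSpec(10.0, step_ref=0.14)
        sim = SimParams(n_particles=2000, open_time=40.0, n_replicates=6,
                        seed=9)
        r_const = simulate_loading(small_cell, mol, sim)
        r_shrink = simulate_loading(shrink, mol, sim)
        assert r_shrink.loading_efficiency < r_const.loading_efficiency


def mc_steps(cell, mol, open_time):
    from optopore.mc import _resolve_dt

    return _resolve_dt(cell, mol, SimParams(n_particles=1,
                                            open_time=open_time))[1]


class TestGridHelpers:
    def test_time_grid_starts_at_zero(self, small_cell, fast_sim):
        table = loading_vs_time([0.0, 20.0], MoleculeSpec(10.0), small_cell,
                                fast_sim)
        assert table.loading_mean.iloc[0] == 0.0

    def test_single_point_grid_equals_direct_call(self, small_cell):
        sim = SimParams(n_particles=500, open_time=25.0, n_replicates=3,
                        seed=4)
        table = loading_vs_time([25.0], MoleculeSpec(10.0), small_cell, sim)
        direct = simulate_loading(small_cell, MoleculeSpec(10.0), sim)
        assert table.loading_mean.iloc[0] == direct.loading_efficiency

    def test_empty_grids_rejected(self, small_cell, fast_sim):
        with pytest.raises(ValueError):
            loading_vs_time([], MoleculeSpec(10.0), small_cell, fast_sim)
        with pytest.raises(ValueError):
            loading_vs_mw([], 10.0, small_cell, fast_sim)


class TestCalibrateStep:
    def test_anchor_reproduced_and_deterministic(self, small_cell):
        sim = SimParams(n_particles=1000, open_time=40.0, n_replicates=4,
                        seed=10)
        s1 = calibrate_step(10.0, 40.0, 0.2, small_cell, sim, tol=0.015)
        s2 = calibrate_step(10.0, 40.0, 0.2, small_cell, sim, tol=0.015)
        assert s1 == s2
        mol = MoleculeSpec(10.0, step_ref=s1)
        achieved = simulate_loading(
            small_cell, mol, SimParams(n_particles=1000, open_time=40.0,
                                       n_replicates=4, seed=10))
        assert achieved.loading_efficiency == pytest.approx(0.2, abs=0.015)

    def test_loading_monotone_in_step_scale(self, small_cell):
        loadings = []
        for s in (0.05, 0.15, 0.45):
            mol = MoleculeSpec(10.0, step_ref=s)
            res = simulate_loading(
                small_cell, mol, SimParams(n_particles=1000, open_time=30.0,
                                           n_replicates=10, seed=11))
            loadings.append(res.loading_efficiency)
        assert loadings[0] < loadings[1] < loadings[2]

    def test_unattainable_target_reports_bracket(self, small_cell):
        sim = SimParams(n_particles=200, open_time=5.0, n_replicates=2,
                        seed=12)
        with pytest.raises(ValueError, match="bracket"):
            calibrate_step(10.0, 5.0, 0.999, small_cell, sim,
                           bracket=(0.01, 0.05))
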