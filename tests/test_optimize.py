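"""Optimization formalism: cost closed forms, parameterizations, PSO."""

import copy

import numpy as np
import pytest

from nervesim.errors import InvalidParameterError, OptimizerError
from nervesim.optimize import (CostFunction, EnergyRecruitmentCost,
                               WaveformParameterization,
                               energy_recruitment_cost, pso_optimize,
                               square_pulse_modifier, stimulus_energy,
                               stimulus_energy_dt)
from nervesim.stimulus import Stimulus, make_pulse


class TestEnergyRecruitmentCost:
    def test_zero_stimulus_zero_recruited(self):
        p = EnergyRecruitmentCost(alpha_e=1e-3, alpha_r=2.0, n_axon=205)
        assert energy_recruitment_cost(0.0, 0, p) == pytest.approx(
            2.0 * 205)

    def test_full_recruitment_leaves_energy_only(self):
        p = EnergyRecruitmentCost(alpha_e=0.5, alpha_r=10.0, n_axon=100)
        assert energy_recruitment_cost(8.0, 100, p) == pytest.approx(4.0)

    def test_energy_term_quadratic_in_amplitude(self):
        dt = 0.01
        s1 = make_pulse(0.0, -11.0, 0.232)
        s2 = make_pulse(0.0, -22.0, 0.232)
        e1 = stimulus_energy(s1, dt, t_stop=0.5)
        e2 = stimulus_energy(s2, dt, t_stop=0.5)
        assert e2 == pytest.approx(4.0 * e1)

    def test_energy_sum_counts_steps_without_dt_weight(self):
        # a constant −2 µA over exactly 10 steps of the grid
        dt = 0.1
        s = Stimulus([0.0, 1.0], [-2.0, 0.0], "hold")
        e = stimulus_energy(s, dt, t_stop=1.0)
        assert e == pytest.approx(4.0 * 10)
        assert stimulus_energy_dt(s, dt, t_stop=1.0) == pytest.approx(
            e * dt)

    def test_recruitment_dominates_when_alpha_r_large(self):
        # any fully recruiting candidate beats any candidate missing a
        # fiber, given the energy bound implied by the box bounds
        bound_energy = 100.0 ** 2 * 200    # amp² × max steps
        p = EnergyRecruitmentCost(alpha_e=1.0,
                                  alpha_r=2.0 * bound_energy,
                                  n_axon=10)
        full = energy_recruitment_cost(bound_energy, 10, p)
        missing = energy_recruitment_cost(0.0, 9, p)
        assert full < missing


class TestWaveformParameterization:
    def test_square_pulse_events(self):
        par = WaveformParameterization("square", t_start=0.0, t_end=1.0)
        s = par.build_stimulus([11.0, 0.232])
        assert s.times == pytest.approx([0.0, 0.232])
        assert s.values == pytest.approx([-11.0, 0.0])

    def test_spline_single_knot_peak(self):
        par = WaveformParameterization("spline_1", t_start=0.0,
                                       t_end=1.0, dt_sample=0.002)
        s = par.build_stimulus([8.0, 0.5])
        t = np.linspace(0, 1, 501)
        v = s.evaluate(t)
        assert v.min() == pytest.approx(-8.0, abs=0.05)
        assert t[np.argmin(v)] == pytest.approx(0.5, abs=0.01)
        assert abs(v[0]) < 1e-9 and abs(v[-1]) < 1e-9
        assert np.all(v <= 1e-12)          # cathodic only

    def test_spline_knot_order_invariance(self):
        par = WaveformParameterization("spline_2", t_end=1.0)
        a = par.build_stimulus([5.0, 0.7, 3.0, 0.2])
        b = par.build_stimulus([3.0, 0.2, 5.0, 0.7])
        t = np.linspace(0, 1, 200)
        assert a.evaluate(t) == pytest.approx(b.evaluate(t))

    def test_dimension_contract(self):
        assert WaveformParameterization("square").dimension == 2
        assert WaveformParameterization("spline_3").dimension == 6
        with pytest.raises(InvalidParameterError):
            WaveformParameterization("spline_2").build_stimulus([1.0])

    def test_modifier_never_mutates_static_context(self):
        class Ctx:
            def __init__(self):
                self.stim = None
        static = Ctx()
        par = WaveformParameterization("square", t_end=1.0)

        def attach(ctx, stim):
            ctx.stim = stim
        modify = square_pulse_modifier(par, attach)
        before = copy.deepcopy(static.__dict__)
        out = modify(np.array([5.0, 0.1]), static)
        assert out is not static
        assert static.__dict__ == before
        assert out.stim is not None


class TestPSO:
    def test_sphere_convergence(self):
        costs = []
        for seed in range(5):
            x, f, _ = pso_optimize(lambda v: float(np.sum(v * v)),
                                   (np.full(2, -5.0), np.full(2, 5.0)),
                                   n_particles=25, n_iterations=60,
                                   seed=seed)
            costs.append(f)
        assert np.mean(costs) < 1e-3

    def test_best_trace_nonincreasing(self):
        _, _, trace = pso_optimize(
            lambda v: float(np.sum(np.abs(v))) + np.sin(10 * v[0]),
            (np.array([-3.0]), np.array([3.0])),
            n_particles=10, n_iterations=30, seed=1)
        assert np.all(np.diff(trace["best"]) <= 1e-15)

    def test_zero_iterations_returns_initial_best(self):
        rng_cost = lambda v: float(np.sum(v * v))
        x, f, trace = pso_optimize(rng_cost,
                                   (np.full(3, -1.0), np.full(3, 1.0)),
                                   n_particles=8, n_iterations=0, seed=2)
        assert trace["best"].size == 1
        assert f == pytest.approx(rng_cost(x))

    def test_iterates_stay_in_bounds(self):
        seen = []

        def cost(v):
            seen.append(v.copy())
            return float(np.sum(v * v))

        lo, hi = np.array([-2.0, 0.5]), np.array([1.0, 4.0])
        pso_optimize(cost, (lo, hi), n_particles=6, n_iterations=15,
                     seed=3)
        arr = np.array(seen)
        assert np.all(arr >= lo - 1e-12) and np.all(arr <= hi + 1e-12)

    def test_reproducible_under_seed(self):
        f = lambda v: float(np.sum(v * v))
        r1 = pso_optimize(f, (np.full(2, -1.0), np.full(2, 1.0)),
                          n_particles=5, n_iterations=10, seed=11)
        r2 = pso_optimize(f, (np.full(2, -1.0), np.full(2, 1.0)),
                          n_particles=5, n_iterations=10, seed=11)
        assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1]

    def test_all_failures_raise(self):
        with pytest.raises(OptimizerError):
            pso_optimize(lambda v: float("nan"),
                         (np.array([-1.0]), np.array([1.0])),
                         n_particles=4, n_iterations=2, seed=0)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(InvalidParameterError):
            pso_optimize(lambda v: 0.0,
                         (np.array([1.0]), np.array([-1.0])))


class TestCostFunction:
    def test_identity_filter_changes_nothing(self):
        calls = {}

        def modifier(vec, ctx):
            return ("ctx", tuple(vec))

        def simulator(ctx):
            return sum(ctx[1])

        cf_default = CostFunction("static", modifier, simulator,
                                  lambda r: r)
        cf_identity = CostFunction("static", modifier, simulator,
                                   lambda r: r, filter=lambda v: v)
        v = np.array([1.0, 2.5])
        assert cf_default(v) == cf_identity(v) == pytest.approx(3.5)

    def test_deterministic_cost_repeats(self):
        cf = CostFunction(0.0, lambda v, c: np.sum(v) + c,
                          lambda ctx: ctx ** 2, lambda r: r)
        v = np.array([0.3, 0.4])
        assert cf(v) == cf(v)
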