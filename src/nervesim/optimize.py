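"""Stimulation-optimization formalism and a particle-swarm optimizer.

An optimization problem couples a :class:`CostFunction` — an optional
input filter, a static simulable context, a context modifier that
realizes a candidate vector as a modified copy of that context, and a
cost evaluation mapping the simulation outcome to a scalar — with an
optimizer.  The built-in cost is the energy/recruitment trade-off

    cost = α_e · Σ_k i²(t_k) + α_r · (N_axon − N_recruited)

where the energy sum runs over the discrete solver time steps of the
stimulus (no dt weighting; a dt-weighted variant is provided separately
as ``stimulus_energy_dt``), and α_r ≫ α_e favors full recruitment.

Waveform parameterizations: a cathodic square pulse (amplitude, width;
2 dimensions) and an N-knot spline pulse (N (time, amplitude) knots
interpolated by a monotone-safe cubic clamped to zero at both ends and
clipped to cathodic polarity; 2N dimensions).

The solver is a standard global-best particle swarm (documented
defaults: inertia 0.7, cognitive 1.5, social 1.5, reflecting bounds),
reproducible under a seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import InvalidParameterError, OptimizerError
from .stimulus import Stimulus

__all__ = [
    "CostFunction", "EnergyRecruitmentCost", "energy_recruitment_cost",
    "stimulus_energy", "stimulus_energy_dt", "square_pulse_modifier",
    "spline_pulse_modifier", "WaveformParameterization", "pso_optimize",
    "Problem",
]


# ---------------------------------------------------------------------------
# cost evaluation
# ---------------------------------------------------------------------------

def stimulus_energy(stimulus, dt, t_start=0.0, t_stop=None):
    """Σ_k i²(t_k) over the solver's discrete time grid (µA²)."""
    if t_stop is None:
        t_stop = float(stimulus.times[-1]) if len(stimulus) else 0.0
    n = int(round((t_stop - t_start) / dt))
    t = t_start + np.arange(n + 1) * dt
    i = stimulus.evaluate(t)
    return float(np.sum(i * i))


def stimulus_energy_dt(stimulus, dt, t_start=0.0, t_stop=None):
    """dt-weighted energy ∫ i² dt ≈ Σ i²·dt (µA²·ms); the physically
    scaled variant of :func:`stimulus_energy`."""
    return stimulus_energy(stimulus, dt, t_start, t_stop) * dt


@dataclass
class EnergyRecruitmentCost:
    """Weights of the energy/recruitment cost; α_r ≫ α_e is typical."""

    alpha_e: float = 1e-3
    alpha_r: float = 1.0
    n_axon: int = 1

    def __call__(self, energy_sum, n_recruited):
        return energy_recruitment_cost(energy_sum, n_recruited, self)


def energy_recruitment_cost(energy_sum, n_recruited, params):
    """α_e·Σi² + α_r·(N_axon − N_recruited)."""
    return (params.alpha_e * energy_sum
            + params.alpha_r * (params.n_axon - n_recruited))


# ---------------------------------------------------------------------------
# waveform parameterizations / context modifiers
# ---------------------------------------------------------------------------

@dataclass
class WaveformParameterization:
    """Search-space description for a stimulus waveform.

    ``kind`` is "square" (vector = (I, T), 2-D) or "spline_N"
    (vector = (I₁, t₁, …, I_N, t_N), 2N-D).  ``t_start``/``t_end``
    bound the pulse window (ms); amplitudes are magnitudes of the
    cathodic (negative) phase, µA.
    """

    kind: str
    t_start: float = 0.0
    t_end: float = 1.0
    dt_sample: float = 0.005

    def __post_init__(self):
        if self.kind != "square" and not self.kind.startswith("spline_"):
            raise InvalidParameterError(
                f"unknown parameterization {self.kind!r}")

    @property
    def n_knots(self):
        if self.kind == "square":
            return 0
        return int(self.kind.split("_", 1)[1])

    @property
    def dimension(self):
        return 2 if self.kind == "square" else 2 * self.n_knots

    def build_stimulus(self, vector):
        vector = np.asarray(vector, dtype=float)
        if vector.size != self.dimension:
            raise InvalidParameterError(
                f"vector of length {vector.size} for a "
                f"{self.dimension}-dimensional parameterization")
        if self.kind == "square":
            amp, width = vector
            if width <= 0:
                raise InvalidParameterError("pulse width must be positive")
            return Stimulus([self.t_start, self.t_start + width],
                            [-abs(amp), 0.0], "hold")
        knots = vector.reshape(-1, 2)          # rows (I_k, t_k)
        amps = -np.abs(knots[:, 0])
        times = np.clip(knots[:, 1], self.t_start, self.t_end)
        order = np.argsort(times)
        times, amps = times[order], amps[order]
        # clamp to zero at the window edges; deduplicate knot times
        t_all = np.concatenate(([self.t_start], times, [self.t_end]))
        v_all = np.concatenate(([0.0], amps, [0.0]))
        t_all, idx = np.unique(t_all, return_index=True)
        v_all = v_all[idx]
        if t_all.size < 2:
            return Stimulus([self.t_start, self.t_end], [0.0, 0.0], "hold")
        interp = PchipInterpolator(t_all, v_all)
        n = max(int(np.ceil((self.t_end - self.t_start) / self.dt_sample)),
                4)
        t = np.linspace(self.t_start, self.t_end, n + 1)
        v = np.minimum(interp(t), 0.0)        # cathodic only
        v[-1] = 0.0
        return Stimulus(t, v, "linear")


def square_pulse_modifier(parameterization, attach):
    """Context modifier for the square-pulse parameterization.

    ``attach(context_copy, stimulus)`` wires the stimulus into the
    copied context (e.g. replaces an electrode's waveform).  The
    returned callable never mutates the static context.
    """
    def modify(vector, static_context):
        ctx = copy.deepcopy(static_context)
        attach(ctx, parameterization.build_stimulus(vector))
        return ctx
    return modify


# same machinery handles splines — the parameterization carries the kind
spline_pulse_modifier = square_pulse_modifier


class CostFunction:
    """filter ∘ context-modifier ∘ simulation ∘ cost-evaluation.

    Parameters
    ----------
    static_context : object
        The simulation description to optimize around; never mutated.
    context_modifier : callable(vector, static_context) -> context
    simulator : callable(context) -> result
    cost_evaluation : callable(result) -> float
    filter : callable(vector) -> vector or None (identity by default)
    """

    def __init__(self, static_context, context_modifier, simulator,
                 cost_evaluation, filter=None):
        self.static_context = static_context
        self.context_modifier = context_modifier
        self.simulator = simulator
        self.cost_evaluation = cost_evaluation
        self.filter = filter if filter is not None else lambda v: v

    def __call__(self, vector):
        vec = np.asarray(self.filter(np.asarray(vector, dtype=float)))
        context = self.context_modifier(vec, self.static_context)
        result = self.simulator(context)
        return float(self.cost_evaluation(result))


# ---------------------------------------------------------------------------
# particle swarm
# ---------------------------------------------------------------------------

def pso_optimize(cost, bounds, n_particles=25, n_iterations=60, seed=None,
                 inertia=0.7, cognitive=1.5, social=1.5, pool=None):
    """Global-best particle swarm over a box-bounded search space.

    Parameters
    ----------
    cost : callable(vector) -> float
    bounds : (lower, upper) arrays of equal length
    pool : executor with a ``map`` method or None
        Optional process pool used to evaluate one swarm generation in
        parallel (particle evaluations are independent).

    Returns
    -------
    (best_vector, best_cost, trace) where ``trace`` is a dict with
    per-iteration ``best`` (nonincreasing) and ``mean`` cost arrays.
    """
    lower = np.asarray(bounds[0], dtype=float)
    upper = np.asarray(bounds[1], dtype=float)
    if lower.shape != upper.shape or np.any(lower >= upper):
        raise InvalidParameterError("bounds must satisfy lower < upper")
    if not (np.isfinite(lower).all() and np.isfinite(upper).all()):
        raise InvalidParameterError("bounds must be finite")
    dim = lower.size
    rng = np.random.default_rng(seed)

    def evaluate(xs):
        mapper = pool.map if pool is not None else map
        out = []
        for c in mapper(cost, [x.copy() for x in xs]):
            out.append(float(c))
        arr = np.asarray(out)
        if not np.isfinite(arr).any():
            raise OptimizerError("every candidate evaluation failed")
        return np.where(np.isfinite(arr), arr, np.inf)

    x = rng.uniform(lower, upper, size=(n_particles, dim))
    span = upper - lower
    v = rng.uniform(-span, span, size=(n_particles, dim)) * 0.1
    f = evaluate(x)
    pbest_x, pbest_f = x.copy(), f.copy()
    g = int(np.argmin(f))
    gbest_x, gbest_f = x[g].copy(), float(f[g])
    best_trace = [gbest_f]
    mean_trace = [float(np.mean(f[np.isfinite(f)]))]

    for _ in range(n_iterations):
        r1 = rng.uniform(size=(n_particles, dim))
        r2 = rng.uniform(size=(n_particles, dim))
        v = (inertia * v + cognitive * r1 * (pbest_x - x)
             + social * r2 * (gbest_x - x))
        x = x + v
        # reflect at the bounds
        over = x > upper
        under = x < lower
        x = np.where(over, 2 * upper - x, x)
        x = np.where(under, 2 * lower - x, x)
        v = np.where(over | under, -v, v)
        x = np.clip(x, lower, upper)
        f = evaluate(x)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f:
            gbest_f = float(pbest_f[g])
            gbest_x = pbest_x[g].copy()
        best_trace.append(gbest_f)
        mean_trace.append(float(np.mean(f[np.isfinite(f)])))

    trace = {"best": np.array(best_trace), "mean": np.array(mean_trace)}
    return gbest_x, gbest_f, trace


@dataclass
class Problem:
    """Binds a cost function to optimizer settings; JSON-friendly."""

    cost: CostFunction
    bounds: tuple
    n_particles: int = 25
    n_iterations: int = 60
    seed: int | None = None

    def solve(self, pool=None):
        return pso_optimize(self.cost, self.bounds,
                            n_particles=self.n_particles,
                            n_iterations=self.n_iterations,
                            seed=self.seed, pool=pool)
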