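"""Population simulation plans and multiprocess execution.

Each fiber of a fascicle is an independent computational problem (no
ephaptic coupling), so a population simulation is embarrassingly
parallel: fibers are distributed over a process pool and the results
are identical whatever the worker count.  Per-fiber random streams are
derived from a master seed plus the fiber index, so scheduling never
affects the outcome.
"""

from __future__ import annotations

from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InvalidParameterError, NerveSimError
from .fibers import MyelinatedFiber, UnmyelinatedFiber
from .recording import compute_ecap
from .analysis import detect_propagating_ap
from .solver import SimConfig, simulate_fiber

__all__ = ["SimulationPlan", "build_fibers", "simulate_plan",
           "simulate_fascicle"]


@dataclass
class SimulationPlan:
    """Everything needed to simulate a placed population.

    ``clamps`` are broadcast to every fiber ("all") or to the listed
    fiber indices.  ``fiber_length`` is the common longitudinal extent
    (µm).  ``recorder`` (optional) accumulates the population eCAP.
    ``detect_fraction`` sets where propagation is scored along each
    fiber.
    """

    population: object                   # placed AxonPopulation
    fiber_length: float
    config: SimConfig = field(default_factory=SimConfig)
    context: object = None               # ExtracellularContext or None
    clamps: tuple = ()
    clamp_subset: object = "all"         # "all" or sequence of indices
    recorder: object = None
    detect_fraction: float = 0.9
    workers: int = 1
    seed: int = 0
    node_alignment: str = "aligned"      # or "random"
    keep_results: bool = True
    out_dir: object = None               # write per-fiber results here

    def __post_init__(self):
        if not self.population.placed:
            raise InvalidParameterError(
                "population must be placed before simulation")
        if self.node_alignment not in ("aligned", "random"):
            raise InvalidParameterError(
                f"unknown node alignment {self.node_alignment!r}")


def build_fibers(plan):
    """Instantiate fiber objects for every axon of the plan's population."""
    pop = plan.population
    fibers = []
    for i in range(len(pop)):
        d = float(pop.diameter[i])
        y, z = float(pop.y[i]), float(pop.z[i])
        if pop.myelinated[i]:
            offset = 0.0
            if plan.node_alignment == "random":
                rng = np.random.default_rng((plan.seed, i))
                offset = float(rng.uniform(0.0, 1.0))  # fraction of Δx
            fiber = MyelinatedFiber(d, y=y, z=z, length=plan.fiber_length)
            if offset:
                fiber.node_offset = offset * fiber.morphology.internode_length
        else:
            fiber = UnmyelinatedFiber(d, length=plan.fiber_length, y=y, z=z)
        fibers.append(fiber)
    return fibers


def _fiber_job(args):
    """Worker: simulate one fiber, score propagation, and reduce its
    eCAP contribution so traces never cross the process boundary."""
    (idx, fiber, context, clamps, config, recorder, detect_fraction,
     keep) = args
    try:
        return _fiber_job_inner(idx, fiber, context, clamps, config,
                                recorder, detect_fraction, keep)
    except NerveSimError as exc:
        raise type(exc)(f"fiber {idx}: {exc}") from exc


def _fiber_job_inner(idx, fiber, context, clamps, config, recorder,
                     detect_fraction, keep):
    cfg = config
    if recorder is not None and not cfg.record_Imem:
        cfg = replace(cfg, record_Imem=True)
    if fiber.myelinated and clamps:
        # clamp compartments address nodes of Ranvier: with unaligned
        # node offsets "compartment k" means "k-th node"
        node_idx = fiber.build().node_index
        clamps = tuple(replace(c, compartment=int(node_idx[c.compartment]))
                       for c in clamps)
    result = simulate_fiber(fiber, context=context, clamps=clamps,
                            config=cfg)
    detected, t_cross = detect_propagating_ap(
        result, detect_fraction * fiber.length)
    ecap = None
    if recorder is not None:
        ecap = compute_ecap([result], recorder, fibers=[fiber])
        if not keep:
            result.I_mem = None
    if not keep:
        result.V = None
        result.gates = {}
    return idx, result, bool(detected), t_cross, ecap


def simulate_plan(plan):
    """Run every fiber of the plan; returns a result dict.

    Keys: ``results`` (per-fiber SimResult, trace-free when
    ``keep_results`` is off), ``detected`` (bool array), ``t_cross``,
    ``n_recruited``, ``ecap`` ((n_points, n_t) mV or None), ``t``.
    """
    fibers = build_fibers(plan)
    jobs = []
    subset = (range(len(fibers)) if plan.clamp_subset == "all"
              else set(int(i) for i in plan.clamp_subset))
    for i, fiber in enumerate(fibers):
        clamps = tuple(plan.clamps) if i in subset else ()
        jobs.append((i, fiber, plan.context, clamps, plan.config,
                     plan.recorder, plan.detect_fraction,
                     plan.keep_results))

    n = len(fibers)
    results = [None] * n
    detected = np.zeros(n, dtype=bool)
    t_cross = np.full(n, np.nan)
    ecap_total = None
    t_vec = None

    def consume(out):
        nonlocal ecap_total, t_vec
        idx, result, det, tc, ecap = out
        results[idx] = result
        detected[idx] = det
        t_cross[idx] = tc
        t_vec = result.t
        if ecap is not None:
            ecap_total = ecap if ecap_total is None else ecap_total + ecap
        if plan.out_dir is not None:
            from pathlib import Path

            from .configio import save_result
            save_result(result, Path(plan.out_dir) / f"fiber_{idx:05d}")

    if plan.workers <= 1 or n <= 1:
        for job in jobs:
            consume(_fiber_job(job))
    else:
        with ProcessPoolExecutor(max_workers=plan.workers) as pool:
            for out in pool.map(_fiber_job, jobs, chunksize=1):
                consume(out)

    return {
        "results": results,
        "detected": detected,
        "t_cross": t_cross,
        "n_recruited": int(detected.sum()),
        "ecap": ecap_total,
        "t": t_vec,
        "n_fibers": n,
    }


def simulate_fascicle(fascicle, fiber_length, **plan_kwargs):
    """Convenience wrapper: plan and run a fascicle's population."""
    plan = SimulationPlan(population=fascicle.population,
                          fiber_length=fiber_length, **plan_kwargs)
    return simulate_plan(plan)
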