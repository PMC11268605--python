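"""Configuration files, provenance, and on-disk result format.

A run is described by one JSON document with a ``task`` key naming the
computation and task-specific sections.  Every output embeds the SHA-256
hash of the canonicalized configuration and the package version, so a
result file always identifies the exact inputs that produced it.

Simulation traces are stored as a JSON header plus plain CSV trace
files (one row per recorded instant, one column per compartment).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (ThresholdSearchSpec, activation_threshold,
                       amplitude_latency_fit, block_threshold,
                       recruitment_curve)
from .errors import ConfigError
from .fibers import fiber_from_dict
from .fields import ExtracellularContext, PointSourceElectrode
from .materials import get_material
from .optimize import pso_optimize
from .population import (AxonPopulation, axon_packing,
                         create_axon_population)
from .recording import Recorder
from .solver import Clamp, SimConfig, SimResult, simulate_fiber
from .stimulus import Stimulus, make_pulse, make_sine

__all__ = ["config_hash", "save_result", "load_result", "run_config",
           "TASKS"]


def config_hash(config):
    """SHA-256 of the canonical JSON encoding of a config dict."""
    canon = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config):
    return {"version": __version__, "config_hash": config_hash(config),
            "seed": config.get("seed")}


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def save_result(result, directory, downsample=1):
    """Write a SimResult as header.json + CSV trace files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sl = slice(None, None, downsample)
    header = {
        "t": result.t[sl].tolist(),
        "x": result.x.tolist(),
        "metadata": result.metadata,
        "traces": [],
    }
    def dump(name, arr):
        np.savetxt(directory / f"{name}.csv", arr[sl], delimiter=",",
                   fmt="%.9g")
        header["traces"].append(name)
    if result.V is not None:
        dump("V", result.V)
    if result.I_mem is not None:
        dump("I_mem", result.I_mem)
    for g, arr in result.gates.items():
        dump(f"gate_{g}", arr)
    (directory / "header.json").write_text(json.dumps(header))
    return directory


def load_result(directory):
    directory = Path(directory)
    header = json.loads((directory / "header.json").read_text())
    arrays = {}
    for name in header["traces"]:
        arrays[name] = np.loadtxt(directory / f"{name}.csv",
                                  delimiter=",", ndmin=2)
    gates = {name[5:]: arr for name, arr in arrays.items()
             if name.startswith("gate_")}
    return SimResult(t=np.asarray(header["t"]),
                     x=np.asarray(header["x"]),
                     V=arrays.get("V"),
                     I_mem=arrays.get("I_mem"),
                     gates=gates,
                     metadata=header["metadata"])


# ---------------------------------------------------------------------------
# config execution
# ---------------------------------------------------------------------------

def _require(config, keys, section=None):
    src = config if section is None else config.get(section, {})
    missing = [k for k in keys if k not in src]
    if missing:
        where = f" in section {section!r}" if section else ""
        raise ConfigError(
            f"missing required key(s){where}: {', '.join(missing)}",
            keys=missing)
    return src


def _build_context(spec):
    _require(spec, ["material", "sources"])
    ctx = ExtracellularContext(get_material(spec["material"]))
    for src in spec["sources"]:
        _require(src, ["electrode", "stimulus"])
        ctx.add_source(PointSourceElectrode.from_dict(src["electrode"]),
                       _build_stimulus(src["stimulus"]))
    return ctx


def _build_stimulus(spec):
    if "kind" not in spec:
        return Stimulus.from_dict(spec)
    kind = spec["kind"]
    if kind == "pulse":
        return make_pulse(spec.get("start", 0.0), spec["amplitude"],
                          spec["duration"],
                          spec.get("shape", "monophasic"),
                          spec.get("anodic_ratio", 1.0),
                          spec.get("interphase", 0.0))
    if kind == "sine":
        return make_sine(spec.get("start", 0.0), spec["freq"],
                         spec["amplitude_pp"], spec["duration"],
                         spec.get("dt_sample"))
    raise ConfigError(f"unknown stimulus kind {kind!r}", keys=["kind"])


def _build_sim_config(spec):
    return SimConfig(**{k: spec[k] for k in
                        ("dt", "t_sim", "record_V", "record_gates",
                         "record_Imem", "downsample", "settle")
                        if k in spec})


def _task_simulate_axon(config, out_dir):
    _require(config, ["fiber", "sim"])
    fiber = fiber_from_dict(config["fiber"])
    sim_cfg = _build_sim_config(config["sim"])
    context = (_build_context(config["context"])
               if "context" in config else None)
    clamps = [Clamp(c.get("kind", "current"), c["compartment"],
                    _build_stimulus(c["stimulus"]))
              for c in config.get("clamps", [])]
    result = simulate_fiber(fiber, context=context, clamps=clamps,
                            config=sim_cfg)
    result.metadata["provenance"] = _provenance(config)
    save_result(result, Path(out_dir) / "axon",
                downsample=config.get("output_downsample", 1))
    return {"task": "simulate-axon", "n_comp": int(result.x.size),
            "v_max": float(result.V.max())}


def _task_pack(config, out_dir):
    pop_spec = _require(config, ["n"], section="population")
    pop = create_axon_population(
        pop_spec["n"],
        myelinated_fraction=pop_spec.get("myelinated_fraction", 1.0),
        myelinated_stats=pop_spec.get("myelinated_stats",
                                      "sciatic_myelinated"),
        unmyelinated_stats=pop_spec.get("unmyelinated_stats",
                                        "sciatic_unmyelinated"),
        seed=config.get("seed"))
    placed, radius = axon_packing(pop,
                                  delta_gap=config.get("delta_gap", 0.0),
                                  seed=config.get("seed"))
    placed.to_csv(Path(out_dir) / "population.csv")
    return {"task": "pack", "n": len(placed),
            "fitted_radius_um": radius}


def _task_threshold(config, out_dir):
    _require(config, ["fiber", "electrode", "material", "pulse"])
    fiber = fiber_from_dict(config["fiber"])
    electrode = PointSourceElectrode.from_dict(config["electrode"])
    pulse_spec = config["pulse"]
    shape = make_pulse(pulse_spec.get("start", 0.1), -1.0,
                       pulse_spec["duration"])
    search = ThresholdSearchSpec(**config.get("search", {}))
    sim_cfg = _build_sim_config(config.get("sim", {"t_sim": 3.0}))
    thr = activation_threshold(fiber, electrode, config["material"],
                               shape, config=sim_cfg, spec=search)
    return {"task": "threshold", "threshold_uA": thr,
            "tolerance": search.tolerance}


def _task_block_threshold(config, out_dir):
    _require(config, ["diameter", "freq_khz", "distance_um"])
    search = ThresholdSearchSpec(
        **{"lower": 50.0, "upper": 2000.0, "tolerance": 0.01,
           **config.get("search", {})})
    thr = block_threshold(config["diameter"], config["freq_khz"],
                          config["distance_um"], spec=search)
    return {"task": "block-threshold", "block_threshold_uA_pp": thr}


def _load_population(config, out_dir):
    pop_spec = config.get("population", {})
    if "csv" in pop_spec:
        return AxonPopulation.from_csv(pop_spec["csv"])
    _require(pop_spec, ["n"], )
    pop = create_axon_population(
        pop_spec["n"],
        myelinated_fraction=pop_spec.get("myelinated_fraction", 1.0),
        myelinated_stats=pop_spec.get("myelinated_stats",
                                      "sciatic_myelinated"),
        unmyelinated_stats=pop_spec.get("unmyelinated_stats",
                                        "sciatic_unmyelinated"),
        seed=config.get("seed"))
    placed, _ = axon_packing(pop, delta_gap=config.get("delta_gap", 0.0),
                             seed=config.get("seed"))
    return placed


def _task_simulate_fascicle(config, out_dir):
    from .orchestrate import SimulationPlan, simulate_plan
    _require(config, ["fiber_length", "sim"])
    pop = _load_population(config, out_dir)
    clamps = tuple(Clamp(c.get("kind", "current"), c["compartment"],
                         _build_stimulus(c["stimulus"]))
                   for c in config.get("clamps", []))
    recorder = (Recorder.from_dict(config["recorder"])
                if "recorder" in config else None)
    plan = SimulationPlan(
        population=pop, fiber_length=config["fiber_length"],
        config=_build_sim_config(config["sim"]),
        context=(_build_context(config["context"])
                 if "context" in config else None),
        clamps=clamps, recorder=recorder,
        workers=config.get("workers", 1),
        seed=config.get("seed", 0) or 0,
        keep_results=False)
    out = simulate_plan(plan)
    summary = {"task": "simulate-fascicle", "n_fibers": out["n_fibers"],
               "n_recruited": out["n_recruited"]}
    if out["ecap"] is not None:
        np.savetxt(Path(out_dir) / "ecap.csv",
                   np.column_stack([out["t"], out["ecap"].T]),
                   delimiter=",", fmt="%.9g")
        summary["ecap_file"] = "ecap.csv"
    return summary


def _task_recruit(config, out_dir):
    from .orchestrate import build_fibers, SimulationPlan
    _require(config, ["fiber_length", "electrode", "material", "pulse",
                      "amplitudes"])
    pop = _load_population(config, out_dir)
    plan = SimulationPlan(population=pop,
                          fiber_length=config["fiber_length"],
                          config=_build_sim_config(
                              config.get("sim", {"t_sim": 3.0})))
    fibers = build_fibers(plan)
    electrode = PointSourceElectrode.from_dict(config["electrode"])
    shape = make_pulse(config["pulse"].get("start", 0.1), -1.0,
                       config["pulse"]["duration"])
    material = get_material(config["material"])

    def make_context(amp):
        from .stimulus import scale
        return ExtracellularContext(material, [(electrode,
                                                scale(shape, amp))])

    curve = recruitment_curve(fibers, make_context, config["amplitudes"],
                              config=plan.config)
    np.savetxt(Path(out_dir) / "recruitment.csv",
               np.column_stack([curve.sweep, curve.fraction]),
               delimiter=",", header="amplitude_uA,fraction",
               comments="", fmt="%.9g")
    return {"task": "recruit", "rate": curve.rate,
            "fractions": curve.fraction.tolist()}


def _task_ecap(config, out_dir):
    summary = _task_simulate_fascicle(config, out_dir)
    summary["task"] = "ecap"
    if "ecap_file" in summary and config.get("fit", True):
        data = np.loadtxt(Path(out_dir) / "ecap.csv", delimiter=",")
        fit = amplitude_latency_fit(data[:, 1:].T, data[:, 0],
                                    t0=config.get("t0", 0.0))
        summary["amplitude_latency_slope"] = fit["slope"]
    return summary


def _task_optimize(config, out_dir):
    from .optimize import (CostFunction, EnergyRecruitmentCost,
                           WaveformParameterization, square_pulse_modifier,
                           stimulus_energy)
    from .analysis import detect_propagating_ap
    _require(config, ["fiber", "electrode", "material", "parameterization",
                      "bounds", "sim"])
    fiber = fiber_from_dict(config["fiber"])
    electrode = PointSourceElectrode.from_dict(config["electrode"])
    material = get_material(config["material"])
    sim_cfg = _build_sim_config(config["sim"])
    par = WaveformParameterization(**config["parameterization"])
    weights = EnergyRecruitmentCost(
        **{"n_axon": 1, **config.get("cost", {})})

    static = ExtracellularContext(material)
    static.add_source(electrode, Stimulus())

    def attach(ctx, stim):
        ctx.set_stimulus(electrode.id, stim)

    def simulator(ctx):
        stim = ctx.sources[0][1]
        result = simulate_fiber(fiber, context=ctx, config=sim_cfg)
        detected, _ = detect_propagating_ap(result, 0.9 * fiber.length)
        return weights(stimulus_energy(stim, sim_cfg.dt,
                                       t_stop=sim_cfg.t_sim),
                       int(detected))

    cost = CostFunction(static, square_pulse_modifier(par, attach),
                        simulator, lambda c: c)
    lower, upper = (np.asarray(b, dtype=float) for b in config["bounds"])
    best_x, best_f, trace = pso_optimize(
        cost, (lower, upper),
        n_particles=config.get("n_particles", 25),
        n_iterations=config.get("n_iterations", 60),
        seed=config.get("seed"))
    log = [{"iteration": i, "best": float(b), "mean": float(m)}
           for i, (b, m) in enumerate(zip(trace["best"], trace["mean"]))]
    with open(Path(out_dir) / "optimization.jsonl", "w") as fh:
        for entry in log:
            fh.write(json.dumps(entry) + "\n")
    return {"task": "optimize", "best_vector": best_x.tolist(),
            "best_cost": best_f}


def run_config(config, out_dir):
    """Execute the task named in a config dict; outputs land in out_dir.

    Returns a summary dict (also written to ``summary.json``) embedding
    the config hash, seed, and package version.
    """
    if isinstance(config, (str, Path)):
        config = json.loads(Path(config).read_text())
    if "task" not in config:
        raise ConfigError("config must name a task", keys=["task"])
    task = config["task"]
    if task not in TASKS:
        raise ConfigError(
            f"unknown task {task!r}; available: {sorted(TASKS)}",
            keys=["task"])
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = TASKS[task](config, out_dir)
    summary["provenance"] = _provenance(config)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


TASKS = {
    "simulate-axon": _task_simulate_axon,
    "simulate-fascicle": _task_simulate_fascicle,
    "pack": _task_pack,
    "threshold": _task_threshold,
    "block-threshold": _task_block_threshold,
    "recruit": _task_recruit,
    "ecap": _task_ecap,
    "optimize": _task_optimize,
}
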