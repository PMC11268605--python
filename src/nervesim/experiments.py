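"""Canned end-to-end studies built from the library primitives.

These functions wire together population generation, packing, the cable
solver, analytic recording, and the endpoint analyses into the two
reference experiments the package ships:

* :func:`ecap_amplitude_latency_study` — a synchronously activated
  myelinated population in homogeneous endoneurium recorded at eight
  points along the fascicle surface, yielding the per-point eCAP peak
  amplitude/latency pairs and their log-log slope;
* :func:`khz_block_study` — kilohertz conduction-block thresholds over
  diameter, frequency and electrode distance, with the nodal gating
  signature under supra-threshold drive.
"""

from __future__ import annotations

import numpy as np

from .analysis import (BlockProtocol, ThresholdSearchSpec,
                       amplitude_latency_fit, block_threshold)
from .fibers import MyelinatedFiber
from .orchestrate import SimulationPlan, simulate_plan
from .population import axon_packing, create_axon_population
from .recording import Recorder
from .solver import Clamp, SimConfig, simulate_fiber
from .stimulus import make_pulse, make_sine

__all__ = ["ecap_amplitude_latency_study", "khz_block_study",
           "block_gating_signature"]


def ecap_amplitude_latency_study(n_fibers=100, seed=0, n_points=8,
                                 point_spacing=2500.0, first_point=2500.0,
                                 fiber_length=23000.0, dt=0.0025,
                                 t_sim=4.5, clamp_amplitude=0.006,
                                 clamp_duration=0.05, workers=1,
                                 diameter_stats="sciatic_myelinated",
                                 v_ceiling=80.0):
    """eCAP amplitude–latency experiment on a packed myelinated fascicle.

    ``n_fibers`` myelinated fibers are drawn from ``diameter_stats``,
    packed into a fascicle, and all activated at t = 0 by an
    intracellular current clamp at each fiber's first node of Ranvier.
    The extracellular potential is recorded with point-source footprints
    in homogeneous endoneurium at ``n_points`` points on the fascicle
    surface, spaced ``point_spacing`` µm starting ``first_point`` µm
    from the clamp.  Peak amplitude and latency per point are fitted in
    log-log space with the first point excluded (its signal overlaps
    the activation transient).  The per-point peak search uses a causal
    window: it opens after the clamp transient and no earlier than the
    point's distance divided by ``v_ceiling`` (m/s, chosen faster than
    any fiber in the population), since anything arriving sooner is
    volume-conducted activation artifact rather than a propagating
    spike.

    Returns a dict with the fitted slope, per-point amplitudes (mV) and
    latencies (ms), the eCAP array, and the population used.
    """
    pop = create_axon_population(n_fibers, myelinated_fraction=1.0,
                                 myelinated_stats=diameter_stats,
                                 seed=seed)
    placed, radius = axon_packing(pop, seed=seed)
    recorder = Recorder(
        [(first_point + k * point_spacing, radius, 0.0)
         for k in range(n_points)],
        material="endoneurium", method="psa")
    plan = SimulationPlan(
        population=placed,
        fiber_length=fiber_length,
        config=SimConfig(dt=dt, t_sim=t_sim),
        clamps=(Clamp("current", 0,
                      make_pulse(0.0, clamp_amplitude, clamp_duration)),),
        recorder=recorder,
        workers=workers,
        seed=seed,
        node_alignment="random",
        keep_results=False)
    out = simulate_plan(plan)
    windows = [(max(clamp_duration + 0.01,
                    (first_point + k * point_spacing) / (v_ceiling * 1e3)),
                None) for k in range(n_points)]
    fit = amplitude_latency_fit(out["ecap"], out["t"], t0=0.0,
                                exclude_first=True, window=windows)
    return {
        "slope": fit["slope"],
        "amplitude": fit["amplitude"],
        "latency": fit["latency"],
        "used": fit["used"],
        "ecap": out["ecap"],
        "t": out["t"],
        "n_recruited": out["n_recruited"],
        "n_fibers": n_fibers,
        "fascicle_radius": radius,
        "population": placed,
    }


def khz_block_study(diameters=(7.3, 10.0, 16.0), frequencies=(4.0, 40.0),
                    distances=(1000.0,), tolerance=0.01, protocol=None):
    """Block thresholds over a (diameter, frequency, distance) grid.

    Returns ``{(diameter, freq, distance): threshold µA pp}``.
    """
    protocol = protocol or BlockProtocol()
    out = {}
    for d in diameters:
        for f in frequencies:
            for dist in distances:
                spec = ThresholdSearchSpec(lower=50.0, upper=4000.0,
                                           tolerance=tolerance)
                out[(d, f, dist)] = block_threshold(
                    d, f, dist, spec=spec, protocol=protocol)
    return out


def block_gating_signature(diameter=10.0, freq=4.0, distance=1000.0,
                           amplitude_pp=None, threshold=None,
                           protocol=None, margin=1.3):
    """Nodal gating traces under supra-block-threshold kHz drive.

    Simulates the block protocol at ``margin ×`` the block threshold
    (or an explicit ``amplitude_pp``) and returns the gating traces of
    the node under the electrode during the kHz steady state.
    """
    protocol = protocol or BlockProtocol()
    if amplitude_pp is None:
        if threshold is None:
            threshold = block_threshold(diameter, freq, distance,
                                        protocol=protocol)
        amplitude_pp = margin * threshold
    fiber = MyelinatedFiber(diameter, n_nodes=protocol.n_nodes)
    geom = fiber.build()
    nodes = geom.node_index
    center_node = nodes[len(nodes) // 2]
    from .fields import ExtracellularContext, PointSourceElectrode
    from .materials import Material
    electrode = PointSourceElectrode(
        0, (geom.x[center_node], float(distance), 0.0))
    context = ExtracellularContext(
        Material.isotropic(protocol.sigma, "block-medium"),
        [(electrode,
          make_sine(protocol.hfac_start, freq, amplitude_pp,
                    protocol.hfac_stop - protocol.hfac_start))])
    config = SimConfig(dt=protocol.dt, t_sim=protocol.t_sim,
                       record_gates=True)
    result = simulate_fiber(fiber, context=context, config=config)
    node_pos = int(np.argmin(np.abs(
        geom.x[nodes] - geom.x[center_node])))
    steady = (result.t >= protocol.hfac_start + protocol.settle_window) \
        & (result.t <= protocol.hfac_stop)
    return {
        "t": result.t,
        "steady_mask": steady,
        "gates": {g: arr[:, node_pos] for g, arr in result.gates.items()},
        "V": result.V[:, center_node],
        "amplitude_pp": amplitude_pp,
    }
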