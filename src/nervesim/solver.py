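"""Implicit compartmental cable solver.

Integrates the cable equation for one fiber under extracellular
potential drive and intracellular clamps.

Unmyelinated fibers are a single-cable system in the membrane potential
V.  Myelinated fibers are a double-cable system with two unknowns per
compartment: the axolemma potential V (intracellular minus periaxonal)
and the periaxonal potential W (periaxonal minus extracellular), coupled
through the intracellular and periaxonal axial pathways and the myelin
sheath admittance.  At nodes of Ranvier the sheath is replaced by a
near-short so the periaxonal space communicates directly with the
extracellular medium.

Time stepping is backward Euler for the (linearized) voltage system —
a banded direct solve per step — with gating variables advanced by a
staggered exponential-Euler update, which keeps them in [0, 1] for any
bounded voltage trace and remains stable under kilohertz drive.
The extracellular potential enters as the e_ext term of each
compartment, sampled at compartment centers from footprints that are
computed once per (electrode, fiber) pair.

Every simulation starts from the fiber's resting equilibrium, found by
a short large-step implicit relaxation, so an unstimulated run is a
fixed point of the integrator.

Boundary conditions are sealed ends (zero axial current) at both fiber
ends.  Units: ms, mV, µA, mS, µF.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .errors import (InvalidParameterError, NoPropagationError,
                     SolverFailureError)
from .stimulus import Stimulus

__all__ = ["SimConfig", "Clamp", "SimResult", "simulate_fiber",
           "conduction_velocity"]

# sheath conductance standing in for the absent myelin at nodes, S/cm²;
# ≫ any nodal or periaxonal conductance so the periaxonal potential is
# pinned to the extracellular one there
_NODE_SHUNT = 1.0e4


@dataclass
class SimConfig:
    """Time stepping and recording options.

    dt in ms (default 1 µs, fine enough for 40 kHz drive), t_sim in ms.
    ``downsample`` records every k-th step.  ``settle`` controls the
    initial equilibrium relaxation.
    """

    dt: float = 0.001
    t_sim: float = 5.0
    record_V: bool = True
    record_gates: bool = False
    record_Imem: bool = False
    downsample: int = 1
    settle: bool = True

    def __post_init__(self):
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.t_sim < self.dt:
            raise InvalidParameterError("t_sim must be at least dt")
        if self.downsample < 1:
            raise InvalidParameterError("downsample must be >= 1")

    def to_dict(self):
        return {"dt": self.dt, "t_sim": self.t_sim,
                "record_V": self.record_V,
                "record_gates": self.record_gates,
                "record_Imem": self.record_Imem,
                "downsample": self.downsample, "settle": self.settle}


@dataclass
class Clamp:
    """Intracellular clamp at one compartment.

    ``kind`` is "current" (stimulus in µA, injected into the
    compartment's intracellular node) or "voltage" (stimulus in mV; the
    membrane potential is pinned while t lies within the stimulus event
    window and free outside it).
    """

    kind: str
    compartment: int
    stimulus: Stimulus

    def __post_init__(self):
        if self.kind not in ("current", "voltage"):
            raise InvalidParameterError(f"unknown clamp kind {self.kind!r}")


@dataclass
class SimResult:
    """Traces and metadata of one fiber simulation.

    ``V`` (n_t, n_comp) membrane potential in mV; ``I_mem`` (n_t, n_comp)
    membrane current reaching the extracellular medium per compartment
    in µA (recorded at the same instants as V); ``gates`` maps gate name
    to (n_t, n_active) arrays over the active compartments.
    """

    t: np.ndarray
    x: np.ndarray
    V: np.ndarray | None = None
    gates: dict = field(default_factory=dict)
    I_mem: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)
    kind: np.ndarray | None = None    # section kind per compartment

    def nearest_excitable(self, x_query):
        """Index of the compartment nearest ``x_query`` among those with
        excitable membrane (nodes of Ranvier for myelinated fibers)."""
        if self.kind is not None and np.any(self.kind == 0):
            cand = np.flatnonzero(self.kind == 0)
        else:
            cand = np.arange(self.x.size)
        return int(cand[np.argmin(np.abs(self.x[cand] - x_query))])

    @property
    def dt(self):
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else 0.0

    def same_grid(self, other):
        return (self.t.shape == other.t.shape
                and np.allclose(self.t, other.t))


class _CableSystem:
    """Pre-assembled banded backward-Euler system for one fiber."""

    def __init__(self, fiber, dt):
        geom = fiber.build()
        mem = fiber.membrane
        self.geom = geom
        self.mem = mem
        n = geom.n_comp
        self.n = n
        self.two_layer = geom.two_layer
        self.active = (geom.kind == 0) if geom.two_layer \
            else np.ones(n, dtype=bool)
        self.active_idx = np.flatnonzero(self.active)

        self.a = geom.axial_conductance(mem.rho_axial)       # (n-1,) mS
        sa = np.zeros(n)
        sa[:-1] += self.a
        sa[1:] += self.a
        self.sa = sa

        area = geom.area
        if geom.two_layer:
            cm = np.where(self.active, mem.cm, mem.cm_internode) * area
            gpas = np.zeros(n)
            kinds = geom.kind
            gpas[kinds == 1] = mem.g_mysa * area[kinds == 1]
            gpas[kinds == 2] = mem.g_flut * area[kinds == 2]
            gpas[kinds == 3] = mem.g_stin * area[kinds == 3]
            self.g_pas = gpas
            self.ge_pas = gpas * mem.e_pas
            # myelin admittance between periaxonal space and the medium
            n_mem = 2.0 * geom.n_lamellae       # two membranes per lamella
            g_my = np.where(self.active, _NODE_SHUNT * 1e3,
                            mem.g_myelin_lamella * 1e3 / n_mem)  # mS/cm²
            c_my = np.where(self.active, 0.0, mem.c_myelin_lamella / n_mem)
            self.g_my = g_my * geom.area_myelin
            self.c_my = c_my * geom.area_myelin
            self.p = geom.periaxonal_conductance(mem.rho_axial)
            sp = np.zeros(n)
            sp[:-1] += self.p
            sp[1:] += self.p
            self.sp = sp
        else:
            cm = mem.cm * area
            self.g_pas = np.zeros(n)
            self.ge_pas = np.zeros(n)
        self.cm = cm
        self._set_dt(dt)

    def _set_dt(self, dt):
        self.dt = dt
        self.c_over_dt = self.cm / dt
        self._build_template()

    # -- banded assembly -------------------------------------------------
    def _build_template(self):
        n, a = self.n, self.a
        if not self.two_layer:
            ab = np.zeros((3, n))
            ab[1] = self.c_over_dt + self.sa + self.g_pas
            ab[0, 1:] = -a      # M[i, i+1]
            ab[2, :-1] = -a     # M[i, i-1]
            self.bands = (1, 1)
            self.diag_row = 1
            self.ab0 = ab
            return
        # interleaved unknowns [V0, W0, V1, W1, ...]; bandwidth 3.
        # off[d][i] holds M[i, i+d] indexed by row i.
        m = 2 * n
        iv = np.arange(0, m, 2)
        iw = iv + 1
        off = {d: np.zeros(m) for d in range(-3, 4)}
        ap = a + self.p
        off[0][iv] = self.c_over_dt + self.sa + self.g_pas
        off[0][iw] = self.c_my / self.dt + self.g_my + self.sa + self.sp
        off[1][iv] = self.sa            # V_i row, W_i column
        off[1][iw[:-1]] = -a            # W_i row, V_{i+1} column
        off[-1][iw] = self.sa           # W_i row, V_i column
        off[-1][iv[1:]] = -a            # V_i row, W_{i-1} column
        off[2][iv[:-1]] = -a            # V_i row, V_{i+1}
        off[2][iw[:-1]] = -ap           # W_i row, W_{i+1}
        off[-2][iv[1:]] = -a            # V_i row, V_{i-1}
        off[-2][iw[1:]] = -ap           # W_i row, W_{i-1}
        off[3][iv[:-1]] = -a            # V_i row, W_{i+1}
        off[-3][iw[1:]] = -a            # W_i row, V_{i-1}
        u = l = 3
        ab = np.zeros((u + l + 1, m))
        for d, vals in off.items():
            rows = np.arange(max(0, -d), m - max(0, d))
            ab[u - d, rows + d] = vals[rows]
        self.bands = (l, u)
        self.diag_row = u
        self.ab0 = ab

    def laplacian(self, vec, cond):
        """Axial divergence Σ_j g_ij (vec_j − vec_i), length n."""
        flow = cond * (vec[1:] - vec[:-1])
        out = np.zeros(self.n)
        out[:-1] += flow
        out[1:] -= flow
        return out

    @staticmethod
    def _apply_vclamp(ab, b, bands, row, val):
        l, u = bands
        m = ab.shape[1]
        for d in range(-l, u + 1):
            j = row + d
            if 0 <= j < m:
                ab[u - d, j] = 1.0 if d == 0 else 0.0
        b[row] = val

    def step(self, V, W, gates, e_ext, i_clamp, v_clamp):
        """One backward-Euler step; returns (V', W', gates', I_ext).

        ``e_ext`` is the applied extracellular potential per compartment
        (mV) at the new time; ``i_clamp`` per-compartment injected
        current (µA); ``v_clamp`` dict {compartment: mV}.
        ``I_ext`` is the membrane current delivered to the extracellular
        medium per compartment (µA).
        """
        mem, geom = self.mem, self.geom
        # staggered gating update (exponential Euler at the old voltage)
        v_act = V[self.active_idx]
        rates = mem.rates(v_act)
        new_gates = {}
        for g, (al, be) in rates.items():
            tau = 1.0 / (al + be)
            inf = al * tau
            new_gates[g] = inf + (gates[g] - inf) * np.exp(-self.dt / tau)
        g_act, ge_act = mem.conductance_terms(new_gates)
        area_act = geom.area[self.active_idx]
        G_ion = np.zeros(self.n)
        GE_ion = np.zeros(self.n)
        G_ion[self.active_idx] = g_act * area_act
        GE_ion[self.active_idx] = ge_act * area_act

        lap_e_a = self.laplacian(e_ext, self.a)
        ab = self.ab0.copy()
        if not self.two_layer:
            ab[self.diag_row] += G_ion
            b = self.c_over_dt * V + GE_ion + self.ge_pas \
                + lap_e_a + i_clamp
            for comp, val in v_clamp.items():
                self._apply_vclamp(ab, b, self.bands, comp, val)
            Vn = solve_banded(self.bands, ab, b, overwrite_ab=True,
                              overwrite_b=True, check_finite=False)
            i_ion_new = (G_ion + self.g_pas) * Vn - GE_ion - self.ge_pas
            i_ext = self.cm * (Vn - V) / self.dt + i_ion_new
            return Vn, None, new_gates, i_ext

        lap_e_p = self.laplacian(e_ext, self.p)
        iv = np.arange(0, 2 * self.n, 2)
        ab[self.diag_row, iv] += G_ion
        b = np.empty(2 * self.n)
        b[0::2] = self.c_over_dt * V + GE_ion + self.ge_pas \
            + lap_e_a + i_clamp
        b[1::2] = (self.c_my / self.dt) * W + lap_e_a + lap_e_p + i_clamp
        for comp, val in v_clamp.items():
            self._apply_vclamp(ab, b, self.bands, 2 * comp, val)
        sol = solve_banded(self.bands, ab, b, overwrite_ab=True,
                           overwrite_b=True, check_finite=False)
        Vn = sol[0::2]
        Wn = sol[1::2]
        # current crossing the sheath into the extracellular medium
        i_ext = self.c_my * (Wn - W) / self.dt + self.g_my * Wn
        return Vn, Wn, new_gates, i_ext

    # -- initialization --------------------------------------------------
    def initial_state(self):
        v0 = np.full(self.n, self.mem.v_rest)
        rates = self.mem.rates(v0[self.active_idx])
        gates = {g: a / (a + b) for g, (a, b) in rates.items()}
        w0 = np.zeros(self.n) if self.two_layer else None
        return v0, w0, gates

    def settle(self, max_steps=400, tol=1e-9):
        """Relax to the resting equilibrium with large implicit steps."""
        if not hasattr(self, "_rest"):
            saved_dt = self.dt
            V, W, gates = self.initial_state()
            zeros = np.zeros(self.n)
            for relax_dt in (0.05, 0.5):
                self._set_dt(relax_dt)
                for _ in range(max_steps):
                    Vn, Wn, gates, _ = self.step(V, W, gates, zeros,
                                                 zeros, {})
                    dv = float(np.max(np.abs(Vn - V)))
                    V, W = Vn, Wn
                    if dv < tol:
                        break
            self._rest = (V, W, gates)
            self._set_dt(saved_dt)
        V, W, gates = self._rest
        return (V.copy(), None if W is None else W.copy(),
                {g: arr.copy() for g, arr in gates.items()})


def _sample_clamps(clamps, t_grid, n_comp):
    i_clamp = np.zeros((t_grid.size, n_comp))
    v_clamps = []
    for c in clamps:
        if not 0 <= c.compartment < n_comp:
            raise InvalidParameterError(
                f"clamp compartment {c.compartment} outside fiber "
                f"(n_comp={n_comp})")
        if c.kind == "current":
            i_clamp[:, c.compartment] += c.stimulus.evaluate(t_grid)
        else:
            vals = c.stimulus.evaluate(t_grid)
            window = (t_grid >= c.stimulus.times[0]) \
                & (t_grid <= c.stimulus.times[-1])
            v_clamps.append((c.compartment, vals, window))
    return i_clamp, v_clamps


def simulate_fiber(fiber, context=None, clamps=(), config=None,
                   imem_consumer=None):
    """Integrate one fiber; returns a :class:`SimResult`.

    Parameters
    ----------
    fiber : UnmyelinatedFiber or MyelinatedFiber
    context : ExtracellularContext or None
        Extracellular stimulation sources; footprints are evaluated at
        compartment centers.
    clamps : sequence of Clamp
    config : SimConfig
    imem_consumer : callable(record_index, i_ext_vector) or None
        Streaming hook invoked at every recorded instant with the
        extracellular membrane-current vector (µA); lets the recording
        layer accumulate population signals without storing every trace.
    """
    config = config or SimConfig()
    clamps = tuple(clamps)
    sys_ = _CableSystem(fiber, config.dt)
    n = sys_.n
    n_steps = int(round(config.t_sim / config.dt))
    t_grid = np.arange(n_steps + 1) * config.dt

    if context is not None and len(context) > 0:
        pts = np.column_stack([sys_.geom.x,
                               np.full(n, fiber.y),
                               np.full(n, fiber.z)])
        fp = context.footprints(pts)                        # (S, n) V/A
        i_src = np.array([stim.evaluate(t_grid)
                          for _, stim in context.sources])  # (S, T)

        def e_at(k):
            return (i_src[:, k] @ fp) * 1e-3                # µV → mV
    else:
        zeros_e = np.zeros(n)

        def e_at(k):
            return zeros_e

    i_clamp_mat, v_clamp_list = _sample_clamps(clamps, t_grid, n)

    if config.settle:
        V, W, gates = sys_.settle()
        # equilibrium membrane current: a static baseline (it sums to
        # zero over the fiber) removed from the recorded traces so
        # recordings are referenced to rest
        _, _, _, i_rest = sys_.step(V, W, gates, np.zeros(n),
                                    np.zeros(n), {})
    else:
        V, W, gates = sys_.initial_state()
        i_rest = np.zeros(n)

    rec_steps = np.arange(0, n_steps + 1, config.downsample)
    if rec_steps[-1] != n_steps:
        rec_steps = np.append(rec_steps, n_steps)
    n_rec = rec_steps.size
    V_rec = np.empty((n_rec, n)) if config.record_V else None
    I_rec = np.empty((n_rec, n)) if config.record_Imem else None
    gates_rec = ({g: np.empty((n_rec, sys_.active_idx.size))
                  for g in gates} if config.record_gates else {})
    rec_map = {int(s): j for j, s in enumerate(rec_steps)}

    def record(step, i_ext):
        j = rec_map.get(step)
        if j is None:
            return
        if V_rec is not None:
            V_rec[j] = V
        if I_rec is not None:
            I_rec[j] = i_ext - i_rest
        for g in gates_rec:
            gates_rec[g][j] = gates[g]
        if imem_consumer is not None:
            imem_consumer(j, i_ext - i_rest)

    record(0, i_rest)
    for k in range(1, n_steps + 1):
        v_clamp = {comp: vals[k] for comp, vals, win in v_clamp_list
                   if win[k]}
        V, W, gates, i_ext = sys_.step(V, W, gates, e_at(k),
                                       i_clamp_mat[k], v_clamp)
        if k % 25 == 0 or k == n_steps:
            if not np.isfinite(V).all():
                bad = int(np.flatnonzero(~np.isfinite(V))[0])
                raise SolverFailureError(
                    f"solver diverged at compartment {bad}, "
                    f"t={k * config.dt:.4f} ms",
                    compartment=bad, time=k * config.dt)
        record(k, i_ext)

    meta = {
        "fiber": fiber.to_dict(),
        "config": config.to_dict(),
        "context": context.to_dict() if context is not None else None,
        "n_clamps": len(clamps),
    }
    return SimResult(t=t_grid[rec_steps], x=sys_.geom.x.copy(),
                     V=V_rec, gates=gates_rec, I_mem=I_rec, metadata=meta,
                     kind=sys_.geom.kind.copy())


def _first_upward_crossing(t, v, threshold):
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        return None
    i = idx[0]
    frac = (threshold - v[i]) / (v[i + 1] - v[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def conduction_velocity(result, x1, x2, threshold=0.0):
    """Conduction velocity between positions x1 and x2 (µm) in m/s.

    Uses the first upward crossing of ``threshold`` (mV, default 0) at
    the compartment nearest each position.
    """
    if result.V is None:
        raise InvalidParameterError("result has no voltage traces")
    if np.isclose(x1, x2):
        raise InvalidParameterError("x1 and x2 must differ")
    times = []
    for xq in (x1, x2):
        comp = result.nearest_excitable(xq)
        tc = _first_upward_crossing(result.t, result.V[:, comp], threshold)
        if tc is None:
            raise NoPropagationError(
                f"no action potential detected at x={xq} µm")
        times.append(tc)
    dt_ms = times[1] - times[0]
    if dt_ms == 0:
        raise NoPropagationError("zero propagation delay between positions")
    return abs(x2 - x1) / abs(dt_ms) * 1e-3  # µm/ms → m/s
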