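"""Conductance-based membrane dynamics.

Two active channel sets are implemented:

* the classic squid-axon sodium/potassium/leak set (gates m, h, n) used
  for unmyelinated fibers, referenced to a −65 mV rest potential;
* the mammalian node-of-Ranvier set used at the nodes of the double-cable
  myelinated fiber: fast sodium (m, h), persistent sodium (mp), slow
  potassium (s) and leak, referenced to −80 mV, with rate constants
  already scaled to 36 °C.

Rate constants are in 1/ms, voltages in mV, conductances in mS/cm²,
capacitances in µF/cm².  The kinetic parameters are vendored from the
published model sources (squid-axon formulation; mammalian-node
formulation of the double-cable motor-fiber model) since they are the
de-facto community standards for these fiber types.

Singular points of the rate expressions (where a denominator
``1 − exp(−x/k)`` vanishes) are handled by their analytic limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HHMembrane", "MRGNodeMembrane", "hh_rates", "mrg_node_rates",
           "steady_state_gates", "membrane_currents"]


def _linexp(x, k):
    """x / (1 − exp(−x/k)), with the limit value k at x → 0."""
    x = np.asarray(x, dtype=float)
    u = x / k
    small = np.abs(u) < 1e-7
    safe_u = np.where(small, 1.0, u)
    with np.errstate(over="ignore"):
        generic = x / (1.0 - np.exp(-safe_u))
    return np.where(small, k * (1.0 + u / 2.0), generic)


def hh_rates(v):
    """Squid-axon α/β rate constants at ``v`` (mV), rest −65 mV.

    Returns a dict ``{gate: (alpha, beta)}`` for gates m, h, n (1/ms).
    """
    v = np.asarray(v, dtype=float)
    am = 0.1 * _linexp(v + 40.0, 10.0)
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    an = 0.01 * _linexp(v + 55.0, 10.0)
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return {"m": (am, bm), "h": (ah, bh), "n": (an, bn)}


def mrg_node_rates(v):
    """Mammalian node-of-Ranvier α/β rate constants at 36 °C.

    Gates: m, h (fast Na), mp (persistent Na), s (slow K); 1/ms.
    """
    v = np.asarray(v, dtype=float)
    am = 6.57 * _linexp(v + 20.4, 10.3)
    bm = 0.304 * _linexp(-(v + 25.7), 9.16)
    ah = 0.34 * _linexp(-(v + 114.0), 11.0)
    bh = 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    ap = 0.0353 * _linexp(v + 27.0, 10.2)
    bp = 0.000883 * _linexp(-(v + 34.0), 10.0)
    a_s = 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    b_s = 0.03 / (1.0 + np.exp(-(v + 90.0)))
    return {"m": (am, bm), "h": (ah, bh), "mp": (ap, bp), "s": (a_s, b_s)}


def steady_state_gates(rates):
    """gate_inf = α/(α+β) for every gate of a rates dict."""
    return {g: a / (a + b) for g, (a, b) in rates.items()}


def membrane_currents(v, gates, membrane, dv_dt=None):
    """Per-area membrane current densities for a gate state (µA/cm²).

    Returns ``(i_ion, i_total)`` where ``i_ion`` is the summed ionic
    current Σ g·gateprod·(V − E) + leak and ``i_total`` adds the
    capacitive term ``c_m · dV/dt`` when ``dv_dt`` (mV/ms) is given.
    Inward currents are negative.
    """
    v = np.asarray(v, dtype=float)
    g, ge = membrane.conductance_terms(gates)
    i_ion = g * v - ge
    if dv_dt is None:
        return i_ion, i_ion
    return i_ion, i_ion + membrane.cm * np.asarray(dv_dt, dtype=float)


@dataclass(frozen=True)
class HHMembrane:
    """Active membrane of an unmyelinated fiber (squid-axon kinetics)."""

    cm: float = 1.0            # µF/cm²
    g_na: float = 120.0        # mS/cm²
    g_k: float = 36.0
    g_l: float = 0.3
    e_na: float = 50.0         # mV
    e_k: float = -77.0
    e_l: float = -54.3
    v_rest: float = -65.0
    rho_axial: float = 100.0   # axoplasm resistivity, Ω·cm

    gate_names = ("m", "h", "n")

    def rates(self, v):
        return hh_rates(v)

    def conductance_terms(self, gates, v_unused=None):
        """Linearized ionic current I = G·V − GE (per cm²).

        Returns (G total mS/cm², GE = Σ g_c·E_c µA/cm²) given the gate
        arrays dict.
        """
        m, h, n = gates["m"], gates["h"], gates["n"]
        gna = self.g_na * m ** 3 * h
        gk = self.g_k * n ** 4
        g = gna + gk + self.g_l
        ge = gna * self.e_na + gk * self.e_k + self.g_l * self.e_l
        return g, ge

    def to_dict(self):
        return {"model": "hh"}


@dataclass(frozen=True)
class MRGNodeMembrane:
    """Nodal channel set of the double-cable myelinated fiber (36 °C)."""

    cm: float = 2.0            # µF/cm²
    g_naf: float = 3000.0      # fast Na, mS/cm²
    g_nap: float = 10.0        # persistent Na
    g_ks: float = 80.0         # slow K
    g_l: float = 7.0
    e_na: float = 50.0
    e_k: float = -90.0
    e_l: float = -90.0
    v_rest: float = -80.0
    rho_axial: float = 70.0    # Ω·cm, axoplasm and periaxonal space

    # passive internodal axolemma (per cm²)
    cm_internode: float = 2.0
    g_mysa: float = 1.0
    g_flut: float = 0.1
    g_stin: float = 0.1
    e_pas: float = -80.0

    # myelin sheath, per lamella membrane (two membranes per lamella)
    c_myelin_lamella: float = 0.1    # µF/cm²
    g_myelin_lamella: float = 0.001  # S/cm²

    gate_names = ("m", "h", "mp", "s")

    def rates(self, v):
        return mrg_node_rates(v)

    def conductance_terms(self, gates, v_unused=None):
        m, h, mp, s = gates["m"], gates["h"], gates["mp"], gates["s"]
        gnaf = self.g_naf * m ** 3 * h
        gnap = self.g_nap * mp ** 3
        gks = self.g_ks * s
        g = gnaf + gnap + gks + self.g_l
        ge = (gnaf + gnap) * self.e_na + gks * self.e_k + self.g_l * self.e_l
        return g, ge

    def to_dict(self):
        return {"model": "mrg"}
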