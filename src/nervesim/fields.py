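"""Analytic extracellular stimulation fields.

Point-source electrodes in an infinite homogeneous (an)isotropic medium.
Under the quasi-static approximation, space and time decouple: each
electrode contributes a static *footprint* (transfer resistance, V/A)
that is computed once per (electrode, point) pair, and the potential at
any time is the footprint weighted by the instantaneous electrode
current and summed over electrodes (linear superposition).

Units: positions in µm, conductivity in S/m, currents in µA, potentials
in mV.  All conversions happen inside this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError, SingularityError
from .materials import Material, get_material
from .stimulus import Stimulus

__all__ = ["PointSourceElectrode", "ExtracellularContext", "psa_footprint"]

_UM_TO_M = 1e-6
# footprint [V/A] × current [µA] = µV; ÷ 1000 → mV
_UV_TO_MV = 1e-3


@dataclass(frozen=True)
class PointSourceElectrode:
    """Dimensionless current point source at ``position`` (x, y, z) µm."""

    id: int
    position: tuple

    def __post_init__(self):
        object.__setattr__(self, "position",
                           tuple(float(p) for p in self.position))
        if len(self.position) != 3:
            raise InvalidParameterError("position must be (x, y, z)")

    def to_dict(self):
        return {"id": self.id, "position": list(self.position)}

    @classmethod
    def from_dict(cls, d):
        return cls(int(d["id"]), tuple(d["position"]))


def psa_footprint(targets, electrode, material):
    """Point-source footprint(s): transfer resistance in V/A.

    For an isotropic conductivity σ the footprint at distance d is
    ``1/(4πσd)``; for a diagonal anisotropic tensor the denominator
    generalizes to ``4π·sqrt(σyy σzz dx² + σxx σzz dy² + σxx σyy dz²)``,
    which reduces to the isotropic form when the components are equal.

    Parameters
    ----------
    targets : (3,) or (n, 3) array, µm
    electrode : PointSourceElectrode or (3,) position, µm
    material : Material, preset name, or dict
    """
    material = get_material(material)
    pos = np.asarray(
        electrode.position if isinstance(electrode, PointSourceElectrode)
        else electrode, dtype=float)
    pts = np.asarray(targets, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    d = (pts - pos) * _UM_TO_M
    sx, sy, sz = material.sigma_xx, material.sigma_yy, material.sigma_zz
    denom = 4.0 * np.pi * np.sqrt(
        sy * sz * d[:, 0] ** 2 + sx * sz * d[:, 1] ** 2
        + sx * sy * d[:, 2] ** 2)
    if np.any(denom == 0.0):
        raise SingularityError(
            "footprint requested at the electrode position")
    fp = 1.0 / denom
    return float(fp[0]) if scalar else fp


class ExtracellularContext:
    """A material plus (electrode, stimulus) pairs; evaluates V_ext(r, t).

    Footprints are cached per (electrode id, point set) and reused across
    time steps; :meth:`clear_cache` forces recomputation after geometry
    changes.
    """

    def __init__(self, material="endoneurium", sources=()):
        self.material = get_material(material)
        self._sources = []
        self._cache = {}
        for electrode, stim in sources:
            self.add_source(electrode, stim)

    @property
    def sources(self):
        return list(self._sources)

    def add_source(self, electrode, stimulus):
        if not isinstance(electrode, PointSourceElectrode):
            electrode = PointSourceElectrode(*electrode)
        if not isinstance(stimulus, Stimulus):
            raise InvalidParameterError("stimulus must be a Stimulus")
        if any(e.id == electrode.id for e, _ in self._sources):
            raise InvalidParameterError(
                f"duplicate electrode id {electrode.id}")
        self._sources.append((electrode, stimulus))

    def set_stimulus(self, electrode_id, stimulus):
        """Replace the stimulus attached to an electrode (footprints kept)."""
        for i, (e, _) in enumerate(self._sources):
            if e.id == electrode_id:
                self._sources[i] = (e, stimulus)
                return
        raise InvalidParameterError(f"no electrode with id {electrode_id}")

    def __len__(self):
        return len(self._sources)

    def clear_cache(self):
        self._cache.clear()

    def footprints(self, points):
        """Footprint matrix, shape (n_sources, n_points), V/A (cached)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        key = pts.tobytes()
        rows = []
        for electrode, _ in self._sources:
            ck = (electrode.id, electrode.position, key)
            if ck not in self._cache:
                self._cache[ck] = psa_footprint(pts, electrode, self.material)
            rows.append(self._cache[ck])
        return np.array(rows) if rows else np.empty((0, pts.shape[0]))

    def currents(self, t):
        """Stimulation currents of all sources at time(s) t, µA."""
        t = np.asarray(t, dtype=float)
        return np.array([stim.evaluate(t) for _, stim in self._sources])

    def field_at(self, points, t):
        """Extracellular potential at ``points`` (µm) and time(s) ``t`` (ms).

        Returns mV with shape (n_points,) for scalar ``t`` or
        (n_points, n_times) for an array.
        """
        if not self._sources:
            raise InvalidParameterError("context has no sources")
        fp = self.footprints(points)                       # (S, P)
        t_arr = np.asarray(t, dtype=float)
        i_stim = np.array([np.atleast_1d(stim.evaluate(t_arr))
                           for _, stim in self._sources])  # (S, T)
        v = fp.T @ i_stim * _UV_TO_MV                      # (P, T)
        return v[:, 0] if t_arr.ndim == 0 else v

    def to_dict(self):
        return {
            "material": self.material.to_dict(),
            "sources": [{"electrode": e.to_dict(), "stimulus": s.to_dict()}
                        for e, s in self._sources],
        }

    @classmethod
    def from_dict(cls, d):
        ctx = cls(Material.from_dict(d["material"]))
        for src in d.get("sources", []):
            ctx.add_source(PointSourceElectrode.from_dict(src["electrode"]),
                           Stimulus.from_dict(src["stimulus"]))
        return ctx
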