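"""Analytic reconstruction of extracellular recordings (eCAPs).

The potential generated by fiber activity at a recording point is the
sum, over fibers and compartments, of each compartment's membrane
current weighted by a static transfer resistance (footprint) between
the compartment and the point — the recording-side mirror of the
stimulation footprint.  Two footprints are available:

* PSA — each compartment is a point source; identical functional form
  to the stimulation footprint, valid for (an)isotropic media;
* LSA — each compartment is a finite line of current along the fiber
  axis; isotropic media only.  The line-source transfer resistance for
  a segment spanning [x₀, x₁] at transverse distance r from the
  recording point is

      1/(4πσ(x₁−x₀)) · [asinh((x₁−x_rec)/r) − asinh((x₀−x_rec)/r)]

  which is the stable form of the usual logarithmic expression and
  converges to the PSA value at the segment midpoint as the segment
  shrinks.

The recording medium is a single homogeneous material (endoneurium by
default).  The stimulation artifact can be superposed by evaluating the
stimulation context at the recording points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import (AlignmentError, InvalidParameterError, SingularityError)
from .fields import psa_footprint
from .materials import get_material

__all__ = ["RecordingPoint", "Recorder", "recorder_footprint_psa",
           "recorder_footprint_lsa", "compute_ecap"]

_UM_TO_M = 1e-6
_UV_TO_MV = 1e-3


@dataclass(frozen=True)
class RecordingPoint:
    """A position in space where the extracellular potential is read."""

    position: tuple
    id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "position",
                           tuple(float(p) for p in self.position))
        if len(self.position) != 3:
            raise InvalidParameterError("position must be (x, y, z)")


def recorder_footprint_psa(point, compartment_position, material):
    """Point-source recording footprint, V/A (same form as stimulation)."""
    return psa_footprint(np.asarray(compartment_position, dtype=float),
                         point.position if isinstance(point, RecordingPoint)
                         else point, material)


def recorder_footprint_lsa(point, segment, material):
    """Line-source recording footprint, V/A; isotropic material only.

    ``segment`` is (x_start, x_end, y, z) in µm describing a current
    line parallel to the x axis.
    """
    material = get_material(material)
    if not material.is_isotropic:
        raise InvalidParameterError(
            "the line-source approximation requires an isotropic material")
    x0, x1, y, z = (float(v) for v in segment)
    if x1 <= x0:
        raise InvalidParameterError("segment must have positive length")
    px, py, pz = (point.position if isinstance(point, RecordingPoint)
                  else tuple(point))
    r = np.hypot(y - py, z - pz) * _UM_TO_M
    if r == 0.0:
        raise SingularityError("recording point lies on the segment axis")
    dl = (x1 - x0) * _UM_TO_M
    h1 = (x1 - px) * _UM_TO_M
    h0 = (x0 - px) * _UM_TO_M
    sigma = material.sigma
    return float((np.arcsinh(h1 / r) - np.arcsinh(h0 / r))
                 / (4.0 * np.pi * sigma * dl))


class Recorder:
    """Recording points in a homogeneous medium with a footprint method.

    Parameters
    ----------
    points : sequence of RecordingPoint or (x, y, z) tuples, µm
    material : Material or preset name, default "endoneurium"
    method : {"psa", "lsa"}
        LSA requires an isotropic material.
    """

    def __init__(self, points, material="endoneurium", method="psa"):
        self.material = get_material(material)
        method = method.lower()
        if method not in ("psa", "lsa"):
            raise InvalidParameterError(f"unknown method {method!r}")
        if method == "lsa" and not self.material.is_isotropic:
            raise InvalidParameterError(
                "LSA recording requires an isotropic material")
        self.method = method
        self.points = [p if isinstance(p, RecordingPoint)
                       else RecordingPoint(tuple(p), i)
                       for i, p in enumerate(points)]
        if not self.points:
            raise InvalidParameterError("recorder needs at least one point")

    @property
    def n_points(self):
        return len(self.points)

    @property
    def positions(self):
        return np.array([p.position for p in self.points])

    def footprints_for(self, x_centers, lengths, y, z):
        """Footprint matrix (n_points, n_comp), V/A, for one fiber.

        ``x_centers`` and ``lengths`` describe the fiber's compartments
        along x at transverse position (y, z).
        """
        x_centers = np.asarray(x_centers, dtype=float)
        lengths = np.asarray(lengths, dtype=float)
        n = x_centers.size
        out = np.empty((self.n_points, n))
        if self.method == "psa":
            pts = np.column_stack([x_centers, np.full(n, y), np.full(n, z)])
            for i, p in enumerate(self.points):
                out[i] = psa_footprint(pts, p.position, self.material)
            return out
        x0 = x_centers - lengths / 2.0
        x1 = x_centers + lengths / 2.0
        sigma = self.material.sigma
        for i, p in enumerate(self.points):
            px, py, pz = p.position
            r = np.hypot(y - py, z - pz) * _UM_TO_M
            if r == 0.0:
                raise SingularityError(
                    f"recording point {p.id} lies on the fiber axis")
            dl = lengths * _UM_TO_M
            h1 = (x1 - px) * _UM_TO_M
            h0 = (x0 - px) * _UM_TO_M
            out[i] = (np.arcsinh(h1 / r) - np.arcsinh(h0 / r)) \
                / (4.0 * np.pi * sigma * dl)
        return out

    def to_dict(self):
        return {"material": self.material.to_dict(), "method": self.method,
                "points": [list(p.position) for p in self.points]}

    @classmethod
    def from_dict(cls, d):
        return cls(points=d["points"], material=d["material"],
                   method=d.get("method", "psa"))


def compute_ecap(results, recorder, fibers=None, context=None):
    """Summed extracellular potential of fiber activity, (n_points, n_t) mV.

    Parameters
    ----------
    results : sequence of SimResult
        Must have membrane-current traces (``record_Imem=True``) and
        share a common time grid.
    recorder : Recorder
    fibers : sequence of fibers or None
        Supplies each fiber's (y, z); if omitted, positions are read
        from each result's metadata.
    context : ExtracellularContext or None
        If given, the stimulation artifact (the stimulation field
        evaluated at the recording points) is added to the output.
    """
    results = list(results)
    if not results:
        raise InvalidParameterError("no results to record from")
    t = results[0].t
    total = np.zeros((recorder.n_points, t.size))
    for i, res in enumerate(results):
        if not results[0].same_grid(res):
            raise AlignmentError(
                f"result {i} does not share the common time grid")
        if res.I_mem is None:
            raise InvalidParameterError(
                f"result {i} has no membrane-current traces "
                "(simulate with record_Imem=True)")
        if fibers is not None:
            y, z = fibers[i].y, fibers[i].z
        else:
            fd = res.metadata.get("fiber", {})
            y, z = fd.get("y", 0.0), fd.get("z", 0.0)
        lengths = np.empty_like(res.x)
        # compartment lengths from center spacing (uniform within a kind)
        edges = np.empty(res.x.size + 1)
        edges[1:-1] = 0.5 * (res.x[1:] + res.x[:-1])
        edges[0] = res.x[0] - (edges[1] - res.x[0])
        edges[-1] = res.x[-1] + (res.x[-1] - edges[-2])
        lengths = np.diff(edges)
        fp = recorder.footprints_for(res.x, lengths, y, z)   # (P, C)
        total += fp @ res.I_mem.T * _UV_TO_MV
    if context is not None and len(context) > 0:
        total += context.field_at(recorder.positions, t)
    return total


class EcapAccumulator:
    """Streaming eCAP accumulation for population runs.

    Bind one per fiber via :func:`make_consumer`; contributions are
    summed into a shared (n_points, n_t) buffer without retaining
    per-fiber current traces.
    """

    def __init__(self, recorder, n_t):
        self.recorder = recorder
        self.total = np.zeros((recorder.n_points, n_t))

    def make_consumer(self, geometry, y, z):
        fp = self.recorder.footprints_for(geometry.x, geometry.length, y, z)

        def consume(j, i_ext):
            self.total[:, j] += fp @ i_ext * _UV_TO_MV
        return consume

    def add(self, other_total):
        self.total += other_total
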