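"""Fiber morphology and discretization.

Unmyelinated fibers are uniform single-cable cylinders with active
membrane everywhere.  Myelinated fibers follow the double-cable layout:
short active nodes of Ranvier separated by passive internodes, each
internode split into myelin-attachment (MYSA), paranode (FLUT) and six
internode (STIN) segments, with a periaxonal conduction path between the
axolemma and the myelin sheath.

Morphological parameters (node spacing, axon diameter, segment lengths,
lamella count) are published for nine discrete fiber diameters between
5.7 and 16 µm.  Those tabulated values are interpolated here with a
monotone piecewise-cubic (PCHIP) through the table, extended by
proportional anchors at 1 µm and linear anchors at 20 µm, which
guarantees positive and monotone outputs over the whole 1–20 µm domain —
naive polynomial fits of the same table go negative below ~2 µm.

All lengths in µm.  Fibers are laid along the x axis starting at x = 0;
(y, z) is the transverse position in the fascicle plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, InvalidParameterError
from .membranes import HHMembrane, MRGNodeMembrane

__all__ = [
    "MyelinatedMorphology", "mrg_morphology", "MRG_DIAMETER_TABLE",
    "UnmyelinatedFiber", "MyelinatedFiber", "CableGeometry",
    "fiber_from_dict",
]

# Tabulated double-cable morphology (published for 5.7–16 µm fibers).
# Columns: fiber D, axon D, node D, FLUT length, node-to-node length,
# lamella count.  Node length 1 µm and MYSA length 3 µm are constant.
MRG_DIAMETER_TABLE = {
    "fiber_diameter": np.array(
        [5.7, 7.3, 8.7, 10.0, 11.5, 12.8, 14.0, 15.0, 16.0]),
    "axon_diameter": np.array(
        [3.4, 4.6, 5.8, 6.9, 8.1, 8.9, 9.2, 10.0, 10.4]),
    "node_diameter": np.array(
        [1.9, 2.4, 2.8, 3.3, 3.7, 4.2, 4.7, 5.0, 5.5]),
    "flut_length": np.array(
        [35.0, 38.0, 40.0, 46.0, 50.0, 54.0, 56.0, 58.0, 60.0]),
    "internode_length": np.array(
        [500.0, 750.0, 1000.0, 1150.0, 1250.0, 1350.0, 1400.0, 1450.0,
         1500.0]),
    "n_lamellae": np.array(
        [80.0, 100.0, 110.0, 120.0, 130.0, 135.0, 140.0, 145.0, 150.0]),
}

NODE_LENGTH = 1.0
MYSA_LENGTH = 3.0
N_STIN = 6

# periaxonal space width per section kind, µm
PERIAXONAL_WIDTH = {"node": 0.002, "mysa": 0.002, "flut": 0.004,
                    "stin": 0.004}

_MRG_DOMAIN = (1.0, 20.0)


def _augmented_interpolant(values):
    """Monotone PCHIP through the table, anchored at 1 and 20 µm.

    The 1 µm anchor scales the smallest tabulated row proportionally to
    diameter (keeps everything positive); the 20 µm anchor extends the
    last tabulated slope linearly.
    """
    d = MRG_DIAMETER_TABLE["fiber_diameter"]
    lo = values[0] * (1.0 / d[0])
    hi = values[-1] + (values[-1] - values[-2]) / (d[-1] - d[-2]) * (20.0 - d[-1])
    xs = np.concatenate(([1.0], d, [20.0]))
    ys = np.concatenate(([lo], values, [hi]))
    return PchipInterpolator(xs, ys)


_INTERPOLANTS = {k: _augmented_interpolant(v)
                 for k, v in MRG_DIAMETER_TABLE.items()
                 if k != "fiber_diameter"}


@dataclass(frozen=True)
class MyelinatedMorphology:
    """Section dimensions of one myelinated internodal repeat (µm)."""

    fiber_diameter: float
    node_length: float
    internode_length: float      # node-to-node (center-to-center) spacing
    axon_diameter: float         # internal axon diameter at FLUT/STIN
    node_diameter: float         # node and MYSA diameter
    mysa_length: float
    flut_length: float
    stin_length: float           # one of the N_STIN equal segments
    n_stin: int
    n_lamellae: float

    @property
    def stin_total(self):
        return self.stin_length * self.n_stin

    def section_lengths_between_nodes(self):
        """MYSA, FLUT, STIN×n, FLUT, MYSA lengths; sums to
        internode_length − node_length."""
        return ([self.mysa_length, self.flut_length]
                + [self.stin_length] * self.n_stin
                + [self.flut_length, self.mysa_length])


def mrg_morphology(fiber_diameter, n_stin=N_STIN):
    """Interpolated double-cable morphology for ``fiber_diameter`` µm.

    Valid for diameters in [1, 20] µm; all outputs are strictly positive
    over the whole domain and reproduce the published table at the
    tabulated diameters.
    """
    d = float(fiber_diameter)
    if not (_MRG_DOMAIN[0] <= d <= _MRG_DOMAIN[1]):
        raise DomainError(
            f"fiber diameter {d} µm outside calibrated domain "
            f"{_MRG_DOMAIN} µm")
    deltax = float(_INTERPOLANTS["internode_length"](d))
    flut = float(_INTERPOLANTS["flut_length"](d))
    stin_total = deltax - NODE_LENGTH - 2 * MYSA_LENGTH - 2 * flut
    if stin_total <= 0:
        raise DomainError(
            f"degenerate internode at diameter {d} µm")  # pragma: no cover
    return MyelinatedMorphology(
        fiber_diameter=d,
        node_length=NODE_LENGTH,
        internode_length=deltax,
        axon_diameter=float(_INTERPOLANTS["axon_diameter"](d)),
        node_diameter=float(_INTERPOLANTS["node_diameter"](d)),
        mysa_length=MYSA_LENGTH,
        flut_length=flut,
        stin_length=stin_total / n_stin,
        n_stin=n_stin,
        n_lamellae=float(_INTERPOLANTS["n_lamellae"](d)),
    )


SECTION_KINDS = ("node", "mysa", "flut", "stin")


@dataclass
class CableGeometry:
    """Discretized cable: per-compartment geometry for the solver.

    Arrays of length n_comp: ``x`` compartment centers (µm), ``length``
    (µm), ``diameter`` axolemma diameter (µm), ``kind`` index into
    :data:`SECTION_KINDS`, ``area`` axolemma lateral area (cm²),
    ``area_myelin`` outer-sheath area (cm², myelinated only),
    ``peri_width`` periaxonal space width (µm).
    """

    x: np.ndarray
    length: np.ndarray
    diameter: np.ndarray
    kind: np.ndarray
    two_layer: bool
    fiber_diameter: float
    n_lamellae: float = 0.0

    def __post_init__(self):
        um2_to_cm2 = 1e-8
        self.area = np.pi * self.diameter * self.length * um2_to_cm2
        outer = self.fiber_diameter if self.two_layer else self.diameter
        self.area_myelin = np.pi * outer * self.length * um2_to_cm2
        self.peri_width = np.array(
            [PERIAXONAL_WIDTH[SECTION_KINDS[k]] for k in self.kind])

    @property
    def n_comp(self):
        return self.x.size

    @property
    def node_index(self):
        return np.flatnonzero(self.kind == 0)

    def axial_conductance(self, rho_axial):
        """Intracellular axial conductance between neighbors, mS, (n−1,)."""
        # half-compartment resistance: rho (Ω·cm) · (L/2 cm) / (π d²/4 cm²)
        half_r = (rho_axial * (self.length / 2 * 1e-4)
                  / (np.pi * (self.diameter * 1e-4) ** 2 / 4.0))  # Ω
        return 1.0 / (half_r[:-1] + half_r[1:]) * 1e3

    def periaxonal_conductance(self, rho_axial):
        """Periaxonal axial conductance between neighbors, mS, (n−1,)."""
        r_in = self.diameter / 2 * 1e-4
        r_out = (self.diameter / 2 + self.peri_width) * 1e-4
        area = np.pi * (r_out ** 2 - r_in ** 2)          # cm²
        half_r = rho_axial * (self.length / 2 * 1e-4) / area
        return 1.0 / (half_r[:-1] + half_r[1:]) * 1e3


@dataclass
class UnmyelinatedFiber:
    """Uniform unmyelinated fiber with active membrane everywhere.

    ``n_compartments`` defaults to a spatial step of 2.5 % of the passive
    length constant (at least 3 compartments).
    """

    diameter: float
    length: float
    y: float = 0.0
    z: float = 0.0
    n_compartments: int | None = None
    membrane: HHMembrane = field(default_factory=HHMembrane)

    myelinated = False

    def __post_init__(self):
        if self.diameter <= 0 or self.length <= 0:
            raise InvalidParameterError("diameter and length must be > 0")
        if self.n_compartments is None:
            lam = self.length_constant()
            self.n_compartments = max(3, int(np.ceil(self.length
                                                     / (0.025 * lam))))
        if self.n_compartments < 3:
            raise InvalidParameterError("need at least 3 compartments")

    def length_constant(self):
        """Passive length constant λ = sqrt(d / (4 ρ_a g_rest)), µm."""
        g_rest = (self.membrane.g_l) * 1e-3            # S/cm²
        d_cm = self.diameter * 1e-4
        lam_cm = np.sqrt(d_cm / (4.0 * self.membrane.rho_axial * g_rest))
        return lam_cm * 1e4

    def build(self):
        n = self.n_compartments
        dx = self.length / n
        x = (np.arange(n) + 0.5) * dx
        return CableGeometry(
            x=x,
            length=np.full(n, dx),
            diameter=np.full(n, self.diameter),
            kind=np.zeros(n, dtype=int),      # all compartments active
            two_layer=False,
            fiber_diameter=self.diameter,
        )

    def to_dict(self):
        return {"type": "unmyelinated", "diameter": self.diameter,
                "length": self.length, "y": self.y, "z": self.z,
                "n_compartments": self.n_compartments, "model": "hh"}


@dataclass
class MyelinatedFiber:
    """Double-cable myelinated fiber along x, starting with a node at x=0.

    Either ``n_nodes`` or ``length`` must be given: with ``n_nodes`` the
    length is (n_nodes − 1)·Δx + node length; with ``length`` the node
    count is the number of full internodal repeats that fit.
    ``node_offset`` shifts the repeating pattern longitudinally (µm,
    taken modulo the node spacing) to emulate unaligned nodes across a
    population.
    """

    diameter: float
    y: float = 0.0
    z: float = 0.0
    n_nodes: int | None = None
    length: float | None = None
    node_offset: float = 0.0
    membrane: MRGNodeMembrane = field(default_factory=MRGNodeMembrane)

    myelinated = True

    def __post_init__(self):
        self.morphology = mrg_morphology(self.diameter)
        dx = self.morphology.internode_length
        if self.n_nodes is None and self.length is None:
            raise InvalidParameterError("give n_nodes or length")
        if self.n_nodes is None:
            self.n_nodes = max(3, int(np.floor(
                (self.length - self.morphology.node_length) / dx)) + 1)
        if self.n_nodes < 3:
            raise InvalidParameterError("need at least 3 nodes")
        self.length = (self.n_nodes - 1) * dx + self.morphology.node_length

    def build(self):
        m = self.morphology
        kinds = {"node": 0, "mysa": 1, "flut": 2, "stin": 3}
        seq_len, seq_kind, seq_diam = [], [], []

        def add(kind, length, diam):
            seq_kind.append(kinds[kind])
            seq_len.append(length)
            seq_diam.append(diam)

        internode = (
            [("mysa", m.mysa_length, m.node_diameter),
             ("flut", m.flut_length, m.axon_diameter)]
            + [("stin", m.stin_length, m.axon_diameter)] * m.n_stin
            + [("flut", m.flut_length, m.axon_diameter),
               ("mysa", m.mysa_length, m.node_diameter)]
        )
        offset = float(self.node_offset) % m.internode_length
        if offset > 1e-9:
            # start mid-pattern: emit the tail of one internodal repeat
            acc = 0.0
            for kind, ln, dm in internode:
                if acc + ln <= offset + 1e-12:
                    acc += ln
                    continue
                start = max(offset - acc, 0.0)
                part = ln - start
                if part > 1e-6:
                    add(kind, part, dm)
                acc += ln
        for i_node in range(self.n_nodes):
            add("node", m.node_length, m.node_diameter)
            if i_node < self.n_nodes - 1:
                for kind, ln, dm in internode:
                    add(kind, ln, dm)
        length = np.array(seq_len)
        x = np.cumsum(length) - length / 2.0
        return CableGeometry(
            x=x,
            length=length,
            diameter=np.array(seq_diam),
            kind=np.array(seq_kind, dtype=int),
            two_layer=True,
            fiber_diameter=self.diameter,
            n_lamellae=m.n_lamellae,
        )

    def to_dict(self):
        return {"type": "myelinated", "diameter": self.diameter,
                "y": self.y, "z": self.z, "n_nodes": self.n_nodes,
                "node_offset": self.node_offset, "model": "mrg"}


def fiber_from_dict(d):
    """Rebuild a fiber from its JSON dict."""
    kind = d.get("type")
    if kind == "unmyelinated":
        return UnmyelinatedFiber(
            diameter=d["diameter"], length=d["length"],
            y=d.get("y", 0.0), z=d.get("z", 0.0),
            n_compartments=d.get("n_compartments"))
    if kind == "myelinated":
        return MyelinatedFiber(
            diameter=d["diameter"], y=d.get("y", 0.0), z=d.get("z", 0.0),
            n_nodes=d.get("n_nodes"), length=d.get("length"),
            node_offset=d.get("node_offset", 0.0))
    raise InvalidParameterError(f"unknown fiber type {kind!r}")
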