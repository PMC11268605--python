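"""Fiber-population generation, packing, and fascicle/nerve containers.

Populations are drawn from per-type diameter distributions (built-in
families: truncated lognormal, truncated bimodal Gaussian mixtures; the
named presets emulate published sciatic-nerve histology statistics —
a bimodal myelinated distribution on 2–16 µm and a sub-2 µm lognormal
unmyelinated one — without claiming to reproduce any specific fit).

Placement uses an attraction/repulsion packing scheme: fibers start on
a seeded grid and migrate toward the fascicle center with an attraction
step unless they overlap a neighbor, in which case a repulsion step
along the center-to-center direction separates them.  The attraction
speed decays geometrically so the configuration jams into a dense,
overlap-free disk; the fitted fascicle radius is the smallest circle
containing every fiber.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .errors import (ConfigError, InvalidParameterError,
                     PackingFailureError)

__all__ = [
    "AxonPopulation", "Fascicle", "Nerve", "create_axon_population",
    "axon_packing", "DIAMETER_DISTRIBUTIONS",
]


# ---------------------------------------------------------------------------
# diameter distributions
# ---------------------------------------------------------------------------

def _truncated_lognormal(n, rng, mu, sigma, low, high):
    """Exact inverse-CDF sampling of a lognormal truncated to [low, high]."""
    dist = stats.lognorm(s=sigma, scale=np.exp(mu))
    a, b = dist.cdf(low), dist.cdf(high)
    if not b > a:
        raise ConfigError("empty truncation interval for lognormal")
    return dist.ppf(rng.uniform(a, b, size=n))


def _truncated_bimodal(n, rng, weights, means, sds, low, high):
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(weights), size=n, p=weights)
    out = np.empty(n)
    for k, (m, s) in enumerate(zip(means, sds)):
        idx = comp == k
        a, b = (low - m) / s, (high - m) / s
        out[idx] = stats.truncnorm(a, b, loc=m, scale=s).ppf(
            rng.uniform(size=idx.sum()))
    return out


def _uniform(n, rng, low, high):
    return rng.uniform(low, high, size=n)


def _fixed(n, rng, value):
    return np.full(n, float(value))


#: name -> (sampler, default kwargs).  The "sciatic" presets emulate the
#: published mammalian sciatic/tibial histology statistics: a bimodal
#: myelinated distribution and a narrow sub-2 µm unmyelinated one.
DIAMETER_DISTRIBUTIONS = {
    "truncated_lognormal": (_truncated_lognormal,
                            {"mu": 0.7, "sigma": 0.5, "low": 1.0,
                             "high": 16.0}),
    "bimodal": (_truncated_bimodal,
                {"weights": (0.5, 0.5), "means": (4.0, 11.0),
                 "sds": (1.5, 2.0), "low": 2.0, "high": 16.0}),
    "uniform": (_uniform, {"low": 1.0, "high": 16.0}),
    "fixed": (_fixed, {"value": 10.0}),
    "sciatic_myelinated": (_truncated_bimodal,
                           {"weights": (0.7, 0.3), "means": (5.0, 11.0),
                            "sds": (1.7, 2.2), "low": 2.0, "high": 16.0}),
    "sciatic_unmyelinated": (_truncated_lognormal,
                             {"mu": float(np.log(0.9)), "sigma": 0.35,
                              "low": 0.2, "high": 2.0}),
}


def sample_diameters(n, spec, rng):
    """Draw n diameters from a named distribution spec.

    ``spec`` is a name or a dict ``{"name": ..., **params}``.
    """
    if isinstance(spec, str):
        name, params = spec, {}
    elif isinstance(spec, dict):
        spec = dict(spec)
        name = spec.pop("name", None)
        params = spec
    else:
        raise ConfigError(f"cannot interpret distribution spec {spec!r}")
    try:
        sampler, defaults = DIAMETER_DISTRIBUTIONS[name]
    except KeyError:
        raise ConfigError(
            f"unknown diameter distribution {name!r}; available: "
            f"{sorted(DIAMETER_DISTRIBUTIONS)}") from None
    kwargs = {**defaults, **params}
    return sampler(n, rng, **kwargs)


# ---------------------------------------------------------------------------
# population container
# ---------------------------------------------------------------------------

@dataclass
class AxonPopulation:
    """Per-axon records: type, diameter, transverse position.

    ``y``/``z`` are NaN until the population has been placed.
    """

    myelinated: np.ndarray            # bool (n,)
    diameter: np.ndarray              # µm (n,)
    y: np.ndarray = None              # µm (n,) or NaN
    z: np.ndarray = None
    seed: int | None = None

    def __post_init__(self):
        self.myelinated = np.asarray(self.myelinated, dtype=bool)
        self.diameter = np.asarray(self.diameter, dtype=float)
        if np.any(self.diameter <= 0):
            raise InvalidParameterError("diameters must be positive")
        n = self.diameter.size
        if self.y is None:
            self.y = np.full(n, np.nan)
        if self.z is None:
            self.z = np.full(n, np.nan)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)

    def __len__(self):
        return self.diameter.size

    @property
    def placed(self):
        return not np.any(np.isnan(self.y))

    @property
    def radius(self):
        """Per-axon disk radius, µm."""
        return self.diameter / 2.0

    def copy(self):
        return AxonPopulation(self.myelinated.copy(), self.diameter.copy(),
                              self.y.copy(), self.z.copy(), self.seed)

    # -- logical / geometric operations ---------------------------------
    def filter_by_diameter(self, min_diameter=0.0, max_diameter=np.inf):
        keep = (self.diameter >= min_diameter) \
            & (self.diameter <= max_diameter)
        return self._subset(keep)

    def remove_overlapping_with_disk(self, center, radius):
        """Drop axons whose disk intersects the given disk (µm)."""
        cy, cz = center
        d = np.hypot(self.y - cy, self.z - cz)
        keep = d >= (radius + self.radius)
        return self._subset(keep)

    def translate(self, dy, dz):
        out = self.copy()
        out.y = out.y + dy
        out.z = out.z + dz
        return out

    def rotate(self, angle_deg, center=(0.0, 0.0)):
        th = np.deg2rad(angle_deg)
        cy, cz = center
        y, z = self.y - cy, self.z - cz
        out = self.copy()
        out.y = cy + y * np.cos(th) - z * np.sin(th)
        out.z = cz + y * np.sin(th) + z * np.cos(th)
        return out

    def _subset(self, mask):
        return AxonPopulation(self.myelinated[mask], self.diameter[mask],
                              self.y[mask], self.z[mask], self.seed)

    # -- I/O -------------------------------------------------------------
    def to_frame(self):
        return pd.DataFrame({
            "type": np.where(self.myelinated, "myelinated", "unmyelinated"),
            "diameter_um": self.diameter,
            "y_um": self.y,
            "z_um": self.z,
        })

    def to_csv(self, path_or_buf):
        self.to_frame().to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df):
        return cls(df["type"].to_numpy() == "myelinated",
                   df["diameter_um"].to_numpy(dtype=float),
                   df.get("y_um", pd.Series(np.nan, index=df.index))
                     .to_numpy(dtype=float),
                   df.get("z_um", pd.Series(np.nan, index=df.index))
                     .to_numpy(dtype=float))

    @classmethod
    def from_csv(cls, path_or_buf):
        return cls.from_frame(pd.read_csv(path_or_buf))


def create_axon_population(n, myelinated_fraction=1.0,
                           myelinated_stats="sciatic_myelinated",
                           unmyelinated_stats="sciatic_unmyelinated",
                           seed=None):
    """Generate an unplaced axon population.

    Types are drawn Bernoulli(``myelinated_fraction``); diameters are
    drawn from the named per-type distribution.  Reproducible under
    ``seed``.
    """
    if n < 1:
        raise InvalidParameterError("need at least one axon")
    if not 0.0 <= myelinated_fraction <= 1.0:
        raise InvalidParameterError("myelinated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    myel = rng.uniform(size=n) < myelinated_fraction
    diam = np.empty(n)
    n_my = int(myel.sum())
    if n_my:
        diam[myel] = sample_diameters(n_my, myelinated_stats, rng)
    if n - n_my:
        diam[~myel] = sample_diameters(n - n_my, unmyelinated_stats, rng)
    return AxonPopulation(myel, diam, seed=seed)


# ---------------------------------------------------------------------------
# packing
# ---------------------------------------------------------------------------

def axon_packing(population, delta_gap=0.0, max_iter=8000, seed=None,
                 attraction_speed=None, attraction_decay=0.999,
                 repulsion_factor=1.05, tol=1e-3, compaction_fraction=0.7):
    """Pack a population into a dense overlap-free disk around the origin.

    Two phases within the ``max_iter`` budget: a compaction phase
    (attraction toward the center for non-overlapping fibers, repulsion
    for overlapping ones, attraction speed decaying geometrically)
    followed by a repulsion-only relaxation that removes residual
    overlaps.  Returns ``(placed_population, fitted_radius)``.  The
    diameter multiset is preserved; the run is deterministic for a
    fixed seed.

    Raises :class:`PackingFailureError` if overlaps remain at
    ``max_iter``.
    """
    if len(population) == 0:
        raise InvalidParameterError("population is empty")
    rng = np.random.default_rng(seed)
    r = population.radius.copy()
    n = r.size

    # seeded grid initialization, shuffled so types mix spatially; the
    # pitch is set by the rms fiber radius so the starting cloud is
    # already near the target density (repulsion resolves the initial
    # overlaps of the largest fibers)
    pitch = 2.2 * float(np.sqrt(np.mean(r ** 2))) + delta_gap + 0.2
    side = int(np.ceil(np.sqrt(n)))
    gy, gz = np.meshgrid(np.arange(side), np.arange(side))
    grid = np.column_stack([gy.ravel(), gz.ravel()])[:n].astype(float)
    grid -= grid.mean(axis=0)
    grid *= pitch
    order = rng.permutation(n)
    pos = grid[order].copy()

    if n == 1:
        placed = population.copy()
        placed.y, placed.z = np.zeros(1), np.zeros(1)
        return placed, float(r[0])

    if attraction_speed is None:
        attraction_speed = max(0.25 * np.mean(r), 0.05)
    v_att = float(attraction_speed)
    query_r = 2.0 * r.max() + delta_gap

    n_compaction = int(max_iter * compaction_fraction)
    for it in range(max_iter):
        attract = it < n_compaction
        tree = cKDTree(pos)
        pairs = tree.query_pairs(query_r, output_type="ndarray")
        overlapping = np.zeros(n, dtype=bool)
        disp = np.zeros_like(pos)
        if pairs.size:
            i, j = pairs[:, 0], pairs[:, 1]
            dvec = pos[i] - pos[j]
            dist = np.hypot(dvec[:, 0], dvec[:, 1])
            need = r[i] + r[j] + delta_gap
            bad = dist < need
            if np.any(bad):
                i, j, dvec, dist, need = (i[bad], j[bad], dvec[bad],
                                          dist[bad], need[bad])
                dist = np.maximum(dist, 1e-9)
                push = (repulsion_factor * 0.5 * (need - dist)
                        / dist)[:, None] * dvec
                np.add.at(disp, i, push)
                np.add.at(disp, j, -push)
                overlapping[i] = True
                overlapping[j] = True
        if attract:
            free = ~overlapping
            dist_c = np.hypot(pos[free, 0], pos[free, 1])
            nz = dist_c > 1e-12
            step = np.minimum(v_att, dist_c)
            unit = np.zeros((int(free.sum()), 2))
            unit[nz] = pos[free][nz] / dist_c[nz, None]
            disp[free] -= unit * step[:, None]
            v_att *= attraction_decay
        pos += disp
        max_disp = float(np.max(np.hypot(disp[:, 0], disp[:, 1])))
        if not attract and max_disp < tol and not np.any(overlapping):
            break

    n_overlaps = _count_overlaps(pos, r, delta_gap)
    if n_overlaps > 0:
        raise PackingFailureError(
            f"packing failed: {n_overlaps} overlapping pairs after "
            f"{it + 1} iterations", n_overlaps=n_overlaps,
            iterations=it + 1)
    placed = population.copy()
    placed.y, placed.z = pos[:, 0].copy(), pos[:, 1].copy()
    fitted = float(np.max(np.hypot(pos[:, 0], pos[:, 1]) + r))
    return placed, fitted


def _count_overlaps(pos, r, delta_gap, slack=1e-6):
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * r.max() + delta_gap,
                             output_type="ndarray")
    if not pairs.size:
        return 0
    i, j = pairs[:, 0], pairs[:, 1]
    dist = np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1])
    return int(np.sum(dist < r[i] + r[j] + delta_gap - slack))


# ---------------------------------------------------------------------------
# fascicle / nerve containers
# ---------------------------------------------------------------------------

@dataclass
class Fascicle:
    """A circular fiber bundle: center, radius, and its population."""

    center: tuple = (0.0, 0.0)
    radius: float = 0.0
    population: AxonPopulation | None = None

    def __post_init__(self):
        if self.population is not None and self.population.placed:
            self.check_containment()

    def check_containment(self):
        pop = self.population
        cy, cz = self.center
        d = np.hypot(pop.y - cy, pop.z - cz) + pop.radius
        if np.any(d > self.radius * (1.0 + 1e-9) + 1e-9):
            raise InvalidParameterError(
                "population extends beyond the fascicle boundary")

    @classmethod
    def from_packing(cls, population, delta_gap=0.0, seed=None, **kwargs):
        placed, radius = axon_packing(population, delta_gap=delta_gap,
                                      seed=seed, **kwargs)
        return cls(center=(0.0, 0.0), radius=radius, population=placed)


@dataclass
class Nerve:
    """One or more non-overlapping fascicles inside a nerve cylinder."""

    diameter: float
    length: float
    fascicles: list = field(default_factory=list)

    def add_fascicle(self, fascicle):
        cy, cz = fascicle.center
        if np.hypot(cy, cz) + fascicle.radius > self.diameter / 2.0 + 1e-9:
            raise InvalidParameterError(
                "fascicle extends beyond the nerve boundary")
        for other in self.fascicles:
            dist = np.hypot(cy - other.center[0], cz - other.center[1])
            if dist < fascicle.radius + other.radius - 1e-9:
                raise InvalidParameterError("fascicles must not overlap")
        self.fascicles.append(fascicle)
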