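"""Conductive media.

A :class:`Material` is an isotropic or diagonally anisotropic ohmic
conductor, the only electrical description needed under the quasi-static
approximation.  Conductivities are in S/m.  Presets cover the usual
peri-neural tissues: anisotropic bulk endoneurium (high along-fiber
conductivity), epineurium, the highly resistive perineurial sheath, and
physiological saline.  Preset values follow the conductivities commonly
used in peripheral-nerve volume-conductor models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["Material", "get_material", "MATERIAL_PRESETS"]


@dataclass(frozen=True)
class Material:
    """Diagonal conductivity tensor, S/m.

    The x axis is the along-fiber direction of the nerve model.
    """

    sigma_xx: float
    sigma_yy: float
    sigma_zz: float
    name: str = ""

    def __post_init__(self):
        if min(self.sigma_xx, self.sigma_yy, self.sigma_zz) <= 0:
            raise InvalidParameterError(
                "all conductivity components must be positive")

    @classmethod
    def isotropic(cls, sigma, name=""):
        return cls(sigma, sigma, sigma, name)

    @property
    def is_isotropic(self):
        return np.isclose(self.sigma_xx, self.sigma_yy) and \
            np.isclose(self.sigma_xx, self.sigma_zz)

    @property
    def sigma(self):
        """Scalar conductivity; only meaningful for isotropic materials."""
        if not self.is_isotropic:
            raise InvalidParameterError(
                f"material {self.name!r} is anisotropic")
        return self.sigma_xx

    def to_dict(self):
        return {"sigma_xx": self.sigma_xx, "sigma_yy": self.sigma_yy,
                "sigma_zz": self.sigma_zz, "name": self.name}

    @classmethod
    def from_dict(cls, d):
        if "sigma" in d:
            return cls.isotropic(d["sigma"], d.get("name", ""))
        return cls(d["sigma_xx"], d["sigma_yy"], d["sigma_zz"],
                   d.get("name", ""))


#: Longitudinal endoneurium conductivity 0.57 S/m, transverse 0.085 S/m;
#: epineurium 0.085 S/m; perineurium 0.002 S/m; saline 2 S/m.
MATERIAL_PRESETS = {
    "endoneurium": Material(0.57, 0.085, 0.085, "endoneurium"),
    "endoneurium_isotropic": Material.isotropic(0.57, "endoneurium_isotropic"),
    "epineurium": Material.isotropic(0.085, "epineurium"),
    "perineurium": Material.isotropic(0.002, "perineurium"),
    "saline": Material.isotropic(2.0, "saline"),
}


def get_material(spec):
    """Resolve a material from a preset name, dict, or Material."""
    if isinstance(spec, Material):
        return spec
    if isinstance(spec, str):
        try:
            return MATERIAL_PRESETS[spec]
        except KeyError:
            raise InvalidParameterError(
                f"unknown material preset {spec!r}; available: "
                f"{sorted(MATERIAL_PRESETS)}") from None
    if isinstance(spec, dict):
        return Material.from_dict(spec)
    raise InvalidParameterError(f"cannot interpret material spec {spec!r}")
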