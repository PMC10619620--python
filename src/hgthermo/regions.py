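"""Axial region specifications around a host: cavity cylinder and portal slabs.

Hosts considered here are barrel-like macrocycles with a symmetry axis
running portal to portal.  The cavity is modelled as a cylinder about
that axis; the portal regions as two slabs just beyond the cylinder's
flat faces, slightly wider than the cavity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CylinderRegion", "PortalSlabs"]


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    norm = np.linalg.norm(v)
    if norm < 1e-6:
        raise ValueError("degenerate axis vector")
    return v / norm


def _axial_radial(points: np.ndarray, center: np.ndarray, axis: np.ndarray):
    rel = np.atleast_2d(points) - center
    axial = rel @ axis
    radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
    return axial, radial


@dataclass(frozen=True)
class CylinderRegion:
    """Finite cylinder: |axial| <= half_height and radial <= radius."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float = 4.0
    half_height: float = 3.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_height <= 0:
            raise ValueError("radius and half_height must be positive")
        object.__setattr__(self, "axis", tuple(_unit(np.asarray(self.axis))))

    def contains(self, points: np.ndarray) -> np.ndarray:
        axial, radial = _axial_radial(
            points, np.asarray(self.center, float), np.asarray(self.axis, float)
        )
        return (np.abs(axial) <= self.half_height) & (radial <= self.radius)


@dataclass(frozen=True)
class PortalSlabs:
    """Two slabs beyond the cavity faces: half_height < |axial| <= half_height + thickness."""

    center: tuple[float, float, float]
    axis: tuple[float, float, float]
    radius: float = 6.0
    half_height: float = 3.0
    thickness: float = 3.0

    def __post_init__(self) -> None:
        if min(self.radius, self.half_height, self.thickness) <= 0:
            raise ValueError("radius, half_height and thickness must be positive")
        object.__setattr__(self, "axis", tuple(_unit(np.asarray(self.axis))))

    def contains(self, points: np.ndarray) -> np.ndarray:
        axial, radial = _axial_radial(
            points, np.asarray(self.center, float), np.asarray(self.axis, float)
        )
        a = np.abs(axial)
        return (a > self.half_height) & (a <= self.half_height + self.thickness) & (
            radial <= self.radius
        )
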