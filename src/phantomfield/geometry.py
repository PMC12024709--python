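"""Spherical 10-20 montage geometry for phantom depth recordings.

The phantom (a head-sized sphere) carries the 21 electrodes of the
international 10-20 system on its surface.  A rigid rod inserted radially
at each electrode site records at four depths along the insertion line:
the surface (``Z0``), one third and two thirds of the diameter (``Z33``,
``Z66``), and the full diameter (``Z100``).  Plotted on nested spheres,
``Z0``/``Z100`` sit on the outer sphere of radius *R* and ``Z33``/``Z66``
on the inner concentric sphere of radius *R/3*.

All positions are expressed in a right-handed frame with +x toward the
right preauricular point (C4 side), +y toward the nasion and +z toward
the vertex (Cz).  The sphere centre is the internal origin; exported
coordinates are translated so that the recording reference electrode is
at (0, 0, 0).  Angles are degrees in the public API, lengths are mm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ELECTRODES",
    "LEFT_ELECTRODES",
    "RIGHT_ELECTRODES",
    "MIDLINE_ELECTRODES",
    "HOMOLOGUE_PAIRS",
    "DepthLevel",
    "SphereModel",
    "ElectrodeAngles",
    "MontageLayout",
    "ReferenceFrame",
    "RecordingPoint",
    "standard_1020_angles",
    "surface_position",
    "depth_position",
    "translate_to_reference",
    "recording_grid",
    "grid_to_frame",
]

#: Canonical electrode order used for every exported table (row order of
#: all outputs: this order, then depth Z0 < Z33 < Z66 < Z100).
ELECTRODES: tuple[str, ...] = (
    "Fp1", "Fpz", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6", "O1", "Oz", "O2",
)

#: Left/right homologue pairs mirroring through the mid-sagittal plane.
HOMOLOGUE_PAIRS: tuple[tuple[str, str], ...] = (
    ("Fp1", "Fp2"), ("F7", "F8"), ("F3", "F4"), ("T3", "T4"),
    ("C3", "C4"), ("T5", "T6"), ("P3", "P4"), ("O1", "O2"),
)

LEFT_ELECTRODES: frozenset[str] = frozenset(p[0] for p in HOMOLOGUE_PAIRS)
RIGHT_ELECTRODES: frozenset[str] = frozenset(p[1] for p in HOMOLOGUE_PAIRS)
MIDLINE_ELECTRODES: frozenset[str] = frozenset(
    e for e in ELECTRODES if e not in LEFT_ELECTRODES | RIGHT_ELECTRODES
)

# (elevation above the equatorial plane, azimuth from +y [nasion] toward
# +x [right]) in degrees.  The outer ring sits at 18 deg elevation with
# azimuths on the 10-20 percentage spacings; the parasagittal electrodes
# F3/F4/P3/P4 at 36 deg; the central cross Fz/C3/C4/Pz at 54 deg; Cz is
# the pole.  With a 240.80 mm sphere this table reproduces standard
# chord distances (e.g. C3-C4 = 141.54 mm, C3-Cz = 74.41 mm).
_STANDARD_ANGLES: dict[str, tuple[float, float]] = {
    "Fp1": (18.0, -18.0), "Fpz": (18.0, 0.0), "Fp2": (18.0, 18.0),
    "F7": (18.0, -54.0), "F3": (36.0, -36.0), "Fz": (54.0, 0.0),
    "F4": (36.0, 36.0), "F8": (18.0, 54.0),
    "T3": (18.0, -90.0), "C3": (54.0, -90.0), "Cz": (90.0, 0.0),
    "C4": (54.0, 90.0), "T4": (18.0, 90.0),
    "T5": (18.0, -126.0), "P3": (36.0, -144.0), "Pz": (54.0, 180.0),
    "P4": (36.0, 144.0), "T6": (18.0, 126.0),
    "O1": (18.0, -162.0), "Oz": (18.0, 180.0), "O2": (18.0, 162.0),
}


class DepthLevel(enum.IntEnum):
    """Recording depth along the radial insertion line.

    ``Z0`` surface, ``Z33`` one third of the diameter, ``Z66`` two
    thirds, ``Z100`` the full diameter.  The integer values give the
    canonical ordering Z0 < Z33 < Z66 < Z100.
    """

    Z0 = 0
    Z33 = 1
    Z66 = 2
    Z100 = 3

    @property
    def radius_fraction(self) -> float:
        """Radius of the depth sphere as a fraction of the outer radius."""
        return {DepthLevel.Z0: 1.0, DepthLevel.Z33: 1.0 / 3.0,
                DepthLevel.Z66: 1.0 / 3.0, DepthLevel.Z100: 1.0}[self]

    @property
    def beyond_center(self) -> bool:
        """True for depths past the sphere centre (Z66 and Z100)."""
        return self in (DepthLevel.Z66, DepthLevel.Z100)

    @classmethod
    def parse(cls, text: str | "DepthLevel") -> "DepthLevel":
        if isinstance(text, cls):
            return text
        try:
            return cls[str(text).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown depth level {text!r}") from None


@dataclass(frozen=True)
class SphereModel:
    """The perfect-sphere phantom: radius (mm) and centre in the world frame."""

    radius: float
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError(f"sphere radius must be > 0, got {self.radius}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def center_array(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class ElectrodeAngles:
    """Angular placement of one electrode.

    ``elevation`` is the angle above the equatorial plane; ``azimuth``
    is measured from +y (nasion) toward +x (right).  The pole electrode
    (elevation 90) has an arbitrary azimuth.
    """

    label: str
    elevation: float
    azimuth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.elevation <= 90.0:
            raise ValueError(
                f"{self.label}: elevation must be in [0, 90], got {self.elevation}")
        if not -180.0 < self.azimuth <= 180.0:
            raise ValueError(
                f"{self.label}: azimuth must be in (-180, 180], got {self.azimuth}")

    @property
    def unit_vector(self) -> np.ndarray:
        """Outward unit radial vector in the sphere-centred frame."""
        lam = np.deg2rad(self.elevation)
        alp = np.deg2rad(self.azimuth)
        return np.array([
            np.cos(lam) * np.sin(alp),
            np.cos(lam) * np.cos(alp),
            np.sin(lam),
        ])


def standard_1020_angles() -> dict[str, ElectrodeAngles]:
    """Angular table for the 21 electrodes of the 10-20 system."""
    return {
        label: ElectrodeAngles(label, elev, azim)
        for label, (elev, azim) in _STANDARD_ANGLES.items()
    }


def surface_position(angles: ElectrodeAngles, sphere: SphereModel) -> np.ndarray:
    """Cartesian surface position (mm, world frame) of one electrode."""
    return sphere.center_array + sphere.radius * angles.unit_vector


def _mirror(u: np.ndarray) -> np.ndarray:
    """180 deg rotation about the left-right axis: (x, y, z) -> (x, -y, -z)."""
    return np.array([u[0], -u[1], -u[2]])


def depth_position(
    surface_point: np.ndarray,
    sphere: SphereModel,
    depth: DepthLevel,
    projection: str = "mirror",
) -> np.ndarray:
    """Position (mm, world frame) of the recording site at ``depth``.

    The surface point defines the radial insertion direction ``u``.  Depths
    are placed on nested spheres: Z0 at ``R*u``, Z33 at ``(R/3)*u`` and, past
    the centre, Z66 at ``(R/3)*T(u)`` and Z100 at ``R*T(u)``.

    ``projection`` selects the transform ``T`` for the beyond-centre depths:

    ``"mirror"``
        ``T(x, y, z) = (x, -y, -z)`` — a half-turn about the left-right
        axis, which keeps deep points on the insertion electrode's own
        side of the head (ipsilateral bookkeeping).  Default.
    ``"antipode"``
        ``T(u) = -u`` — the physically radial continuation through the
        centre, ending below the contralateral homologue.
    """
    if projection not in ("mirror", "antipode"):
        raise ValueError(f"projection must be 'mirror' or 'antipode', got {projection!r}")
    center = sphere.center_array
    radial = np.asarray(surface_point, dtype=float) - center
    norm = float(np.linalg.norm(radial))
    if abs(norm - sphere.radius) > 1e-6 * sphere.radius:
        raise ValueError(
            f"surface point {surface_point} is not on the sphere "
            f"(|p - c| = {norm:.6f}, radius = {sphere.radius:.6f})")
    u = radial / norm
    depth = DepthLevel(depth)
    if depth.beyond_center:
        u = -u if projection == "antipode" else _mirror(u)
    return center + sphere.radius * depth.radius_fraction * u


@dataclass(frozen=True)
class MontageLayout:
    """A 10-20 montage on a sphere: angles plus derived surface positions."""

    sphere: SphereModel
    angles: Mapping[str, ElectrodeAngles] = field(default_factory=standard_1020_angles)

    def __post_init__(self) -> None:
        if len(self.angles) != len(set(self.angles)):
            raise ValueError("duplicate electrode labels in layout")

    @classmethod
    def standard(cls, diameter_mm: float,
                 center: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "MontageLayout":
        """Standard 21-electrode layout on a sphere of the given diameter."""
        return cls(SphereModel(radius=diameter_mm / 2.0, center=center))

    @property
    def labels(self) -> tuple[str, ...]:
        # canonical order first, then any extra labels in insertion order
        known = [e for e in ELECTRODES if e in self.angles]
        extra = [e for e in self.angles if e not in ELECTRODES]
        return tuple(known + extra)

    def position(self, label: str) -> np.ndarray:
        try:
            ang = self.angles[label]
        except KeyError:
            raise KeyError(f"electrode {label!r} not in layout") from None
        return surface_position(ang, self.sphere)

    def positions(self) -> dict[str, np.ndarray]:
        return {label: self.position(label) for label in self.labels}

    def reference_frame(self, label: str) -> "ReferenceFrame":
        return ReferenceFrame(electrode=label, origin=tuple(self.position(label)))


@dataclass(frozen=True)
class ReferenceFrame:
    """Recording reference: its surface position becomes the origin."""

    electrode: str
    origin: tuple[float, float, float]

    @property
    def origin_array(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)


def translate_to_reference(
    points: Iterable[np.ndarray], reference: ReferenceFrame
) -> list[np.ndarray]:
    """Express world-frame points relative to the recording reference."""
    origin = reference.origin_array
    return [np.asarray(p, dtype=float) - origin for p in points]


@dataclass(frozen=True)
class RecordingPoint:
    """One (electrode, depth) recording site.

    ``position`` is relative to the recording reference (the exported
    frame); ``world`` is the same point in the sphere's world frame;
    ``distance`` is the straight-line distance to the reference origin,
    the denominator of the field estimate EF = dV / distance.
    """

    electrode: str
    depth: DepthLevel
    position: tuple[float, float, float]
    world: tuple[float, float, float]
    distance: float

    @property
    def position_array(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    @property
    def world_array(self) -> np.ndarray:
        return np.asarray(self.world, dtype=float)


def recording_grid(
    layout: MontageLayout,
    reference: ReferenceFrame | str,
    projection: str = "mirror",
) -> list[RecordingPoint]:
    """All (electrode, depth) recording sites in the reference frame.

    Returns ``len(layout.labels) * 4`` points, ordered by the layout's
    canonical electrode order then by depth.
    """
    if isinstance(reference, str):
        reference = layout.reference_frame(reference)
    if reference.electrode not in layout.angles:
        raise KeyError(f"reference electrode {reference.electrode!r} not in layout")
    origin = reference.origin_array
    points: list[RecordingPoint] = []
    for label in layout.labels:
        surf = layout.position(label)
        for depth in DepthLevel:
            world = depth_position(surf, layout.sphere, depth, projection=projection)
            rel = world - origin
            points.append(RecordingPoint(
                electrode=label,
                depth=depth,
                position=tuple(rel),
                world=tuple(world),
                distance=float(np.linalg.norm(rel)),
            ))
    return points


def grid_to_frame(points: Sequence[RecordingPoint]) -> pd.DataFrame:
    """Tabulate recording points as a DataFrame (coordinates in mm)."""
    return pd.DataFrame({
        "electrode": [p.electrode for p in points],
        "depth": [p.depth.name for p in points],
        "x_mm": [p.position[0] for p in points],
        "y_mm": [p.position[1] for p in points],
        "z_mm": [p.position[2] for p in points],
        "distance_mm": [p.distance for p in points],
    })
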