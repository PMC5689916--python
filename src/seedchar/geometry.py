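"""Parametric solid model of cylindrical low-energy brachytherapy seeds.

The seed is modelled as a silver marker rod (the radio-opaque core carrying the
radioactive coating on its surface), a thin coating shell, a vacuum gap, and a
welded titanium capsule whose ends are hemispherical shells.  The long axis of
the seed is the z axis, the origin is the seed centre, and the polar angle
theta is measured from +z so that theta = 90 deg is the transverse plane.

All lengths are centimetres.  Regions partition space::

    marker | coating | capsule_gap | capsule_wall | exterior

The capsule outer solid is the union of a finite cylinder (radius =
``capsule_outer_diameter/2``) and two end balls (radius = ``end_cap_radius``)
centred on the axis at the ends of the cylindrical body; the inner cavity is
the same construction shrunk by the wall thickness.  Because the stated end-cap
radius (0.05 cm) exceeds the tube outer radius (0.04 cm) the weld forms a
slight bulge at each end, which is retained as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "SeedModel",
    "Ray",
    "REGION_NAMES",
    "region_at",
    "region_code",
    "distance_to_boundary",
    "region_volume",
    "load_seed_model",
    "bundled_seed_names",
]

REGION_MARKER = 0
REGION_COATING = 1
REGION_GAP = 2
REGION_WALL = 3
REGION_EXTERIOR = 4

REGION_NAMES = ["marker", "coating", "capsule_gap", "capsule_wall", "exterior"]

_EPS = 1e-9


@dataclass(frozen=True)
class SeedModel:
    """Geometry and materials of a cylindrical encapsulated seed.

    Default field values are the GMS BT-125-1 dimensions: a 3.25 mm x 0.50 mm
    silver marker with a 0.5 um radioactive coating inside a 4.5 mm titanium
    capsule (0.8 mm outer diameter, 0.06 mm wall, hemispherical 0.5 mm end
    welds).
    """

    name: str = "gms-bt-125-1"
    marker_length: float = 0.325
    marker_diameter: float = 0.050
    coating_thickness: float = 0.5e-4
    capsule_length: float = 0.45
    capsule_outer_diameter: float = 0.080
    capsule_wall: float = 0.006
    end_cap_radius: float = 0.050
    coat_end_faces: bool = True
    region_materials: dict = field(
        default_factory=lambda: {
            "marker": "silver",
            "coating": "vacuum",
            "capsule_gap": "vacuum",
            "capsule_wall": "titanium",
        }
    )
    region_densities: dict = field(
        default_factory=lambda: {"marker": 10.53, "capsule_wall": 4.5}
    )

    def __post_init__(self) -> None:
        for fname in (
            "marker_length",
            "marker_diameter",
            "capsule_length",
            "capsule_outer_diameter",
            "capsule_wall",
            "end_cap_radius",
        ):
            if getattr(self, fname) <= 0:
                raise ValueError(f"{fname} must be positive")
        if self.coating_thickness < 0:
            raise ValueError("coating_thickness must be non-negative")
        if self.coating_thickness >= 0.1 * self.marker_diameter:
            raise ValueError("coating_thickness must be small vs marker_diameter")
        if self.marker_length + 2 * self.end_cap_radius > self.capsule_length + _EPS:
            raise ValueError("marker does not fit inside the capsule interior")
        if self.capsule_wall >= self.capsule_outer_diameter / 2:
            raise ValueError("capsule_wall exceeds the capsule radius")

    # -- derived dimensions -------------------------------------------------
    @property
    def marker_radius(self) -> float:
        return self.marker_diameter / 2

    @property
    def marker_half_length(self) -> float:
        return self.marker_length / 2

    @property
    def coat_outer_radius(self) -> float:
        return self.marker_radius + self.coating_thickness

    @property
    def coat_half_length(self) -> float:
        extra = self.coating_thickness if self.coat_end_faces else 0.0
        return self.marker_half_length + extra

    @property
    def capsule_outer_radius(self) -> float:
        return self.capsule_outer_diameter / 2

    @property
    def capsule_inner_radius(self) -> float:
        return self.capsule_outer_radius - self.capsule_wall

    @property
    def body_half_length(self) -> float:
        """Half-length of the cylindrical part of the capsule."""
        return self.capsule_length / 2 - self.end_cap_radius

    @property
    def end_ball_outer_radius(self) -> float:
        return self.end_cap_radius

    @property
    def end_ball_inner_radius(self) -> float:
        return self.end_cap_radius - self.capsule_wall

    def geometry_params(self) -> np.ndarray:
        """Pack the dimensions needed by the transport kernel."""
        return np.array(
            [
                self.marker_radius,
                self.marker_half_length,
                self.coat_outer_radius,
                self.coat_half_length,
                self.capsule_inner_radius,
                self.capsule_outer_radius,
                self.body_half_length,
                self.end_ball_inner_radius,
                self.end_ball_outer_radius,
            ]
        )


@dataclass(frozen=True)
class Ray:
    """A half-line with unit direction; raises on a zero-length direction."""

    origin: tuple
    direction: tuple

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        n = float(np.linalg.norm(d))
        if n == 0.0:
            raise ValueError("ray direction must be non-zero")
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))
        object.__setattr__(self, "direction", tuple(d / n))


def region_code(seed: SeedModel, points) -> np.ndarray:
    """Vectorized region classification; returns integer codes (see REGION_*)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rho2 = x * x + y * y
    az = np.abs(z)

    out = np.full(len(pts), REGION_EXTERIOR, dtype=np.int8)

    # capsule outer solid: cylinder body plus end balls
    bh = seed.body_half_length
    in_outer = (rho2 <= seed.capsule_outer_radius**2) & (az <= bh)
    d2_end = rho2 + (az - bh) ** 2
    in_outer |= d2_end <= seed.end_ball_outer_radius**2
    in_inner = (rho2 <= seed.capsule_inner_radius**2) & (az <= bh)
    in_inner |= d2_end <= seed.end_ball_inner_radius**2

    out[in_outer] = REGION_WALL
    out[in_inner] = REGION_GAP

    in_coat = (rho2 <= seed.coat_outer_radius**2) & (az <= seed.coat_half_length)
    out[in_coat] = REGION_COATING
    in_marker = (rho2 <= seed.marker_radius**2) & (az <= seed.marker_half_length)
    out[in_marker] = REGION_MARKER
    return out


def region_at(seed: SeedModel, point):
    """Region name at a point (or array of points): one of REGION_NAMES."""
    pts = np.asarray(point, dtype=float)
    codes = region_code(seed, pts)
    if pts.ndim == 1:
        return REGION_NAMES[int(codes[0])]
    return np.asarray(REGION_NAMES, dtype=object)[codes]


def _cylinder_ts(ox, oy, dx, dy, radius):
    """Positive ray parameters where rho = radius."""
    a = dx * dx + dy * dy
    if a < 1e-16:
        return ()
    b = ox * dx + oy * dy
    c = ox * ox + oy * oy - radius * radius
    disc = b * b - a * c
    if disc < 0:
        return ()
    sq = math.sqrt(disc)
    return ((-b - sq) / a, (-b + sq) / a)


def _sphere_ts(o, d, center_z, radius):
    oz = o[2] - center_z
    b = o[0] * d[0] + o[1] * d[1] + oz * d[2]
    c = o[0] ** 2 + o[1] ** 2 + oz * oz - radius * radius
    disc = b * b - c
    if disc < 0:
        return ()
    sq = math.sqrt(disc)
    return (-b - sq, -b + sq)


def _plane_ts(oz, dz, z0):
    if abs(dz) < 1e-16:
        return ()
    return ((z0 - oz) / dz, (-z0 - oz) / dz)


def distance_to_boundary(seed: SeedModel, ray: Ray):
    """Distance along ``ray`` to the first region change and the next region.

    Exterior rays that never hit the capsule return ``(inf, "exterior")``.
    Uses the candidate-surface method: the ray can only change region on one of
    the primitive surfaces (cylinders, end planes, end balls), so every
    positive intersection parameter is collected and the nearest one where the
    classification actually changes is returned.
    """
    o = np.asarray(ray.origin, dtype=float)
    d = np.asarray(ray.direction, dtype=float)

    ts: list[float] = []
    for radius in (
        seed.marker_radius,
        seed.coat_outer_radius,
        seed.capsule_inner_radius,
        seed.capsule_outer_radius,
    ):
        ts.extend(_cylinder_ts(o[0], o[1], d[0], d[1], radius))
    for z0 in (
        seed.marker_half_length,
        seed.coat_half_length,
        seed.body_half_length,
    ):
        ts.extend(_plane_ts(o[2], d[2], z0))
    for zc in (seed.body_half_length, -seed.body_half_length):
        for radius in (seed.end_ball_inner_radius, seed.end_ball_outer_radius):
            ts.extend(_sphere_ts(o, d, zc, radius))

    here = int(region_code(seed, o)[0])
    best = math.inf
    nxt = REGION_EXTERIOR
    for t in sorted(t for t in ts if t > 1e-12):
        probe = o + (t + 1e-10) * d
        code = int(region_code(seed, probe)[0])
        if code != here:
            best, nxt = t, code
            break
    if math.isinf(best):
        return math.inf, "exterior"
    return best, REGION_NAMES[nxt]


def _union_solid_volume(cyl_radius: float, half_length: float, ball_radius: float) -> float:
    """Volume of cylinder(|z|<=h, rho<=Rc) union two balls of radius rb at z=+-h."""
    v = math.pi * cyl_radius**2 * (2 * half_length)
    # each ball contributes its outboard half plus the inboard overhang where
    # its cross-section radius exceeds the cylinder radius
    half_ball = (2.0 / 3.0) * math.pi * ball_radius**3
    if ball_radius > cyl_radius:
        delta = math.sqrt(ball_radius**2 - cyl_radius**2)
        overhang = math.pi * ((ball_radius**2 - cyl_radius**2) * delta - delta**3 / 3.0)
    else:
        overhang = 0.0
    return v + 2 * (half_ball + overhang)


def region_volume(seed: SeedModel, region: str) -> float:
    """Closed-form volume (cm^3) of a seed region."""
    if region == "marker":
        return math.pi * seed.marker_radius**2 * seed.marker_length
    if region == "coating":
        coat = math.pi * seed.coat_outer_radius**2 * (2 * seed.coat_half_length)
        return coat - region_volume(seed, "marker")
    inner = _union_solid_volume(
        seed.capsule_inner_radius, seed.body_half_length, seed.end_ball_inner_radius
    )
    outer = _union_solid_volume(
        seed.capsule_outer_radius, seed.body_half_length, seed.end_ball_outer_radius
    )
    if region == "capsule_wall":
        return outer - inner
    if region == "capsule_gap":
        return inner - region_volume(seed, "marker") - region_volume(seed, "coating")
    raise ValueError(f"no closed-form volume for region {region!r}")


def bundled_seed_names() -> list[str]:
    return sorted(_load_bundle().keys())


def _load_bundle() -> dict:
    text = resources.files("seedchar.data").joinpath("seed_models.yaml").read_text()
    return yaml.safe_load(text)


def load_seed_model(name_or_path: str) -> SeedModel:
    """Load a seed model by bundled name (e.g. ``gms-bt-125-1``) or YAML path."""
    bundle = _load_bundle()
    if name_or_path in bundle:
        cfg = dict(bundle[name_or_path])
    else:
        path = Path(name_or_path)
        if not path.exists():
            raise KeyError(
                f"unknown seed model {name_or_path!r}; bundled: {sorted(bundle)}"
            )
        cfg = yaml.safe_load(path.read_text())
        if isinstance(cfg, dict) and len(cfg) == 1 and isinstance(next(iter(cfg.values())), dict):
            ((key, cfg),) = cfg.items()
            cfg = dict(cfg)
            cfg.setdefault("name", key)
    cfg.setdefault("name", name_or_path)
    return SeedModel(**cfg)
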