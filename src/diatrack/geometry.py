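"""Stereo projection model for two orthogonal kV imagers on a rotating gantry.

Room frame (fixed, right-handed, origin at isocenter):

* ``x`` — left-right, positive toward patient left (LR)
* ``y`` — anterior-posterior, positive anterior (AP)
* ``z`` — superior-inferior, positive superior (SI)

The gantry rotates about the SI axis.  At gantry angle 0 the x-ray source
sits anterior of the patient; positive angles rotate the source clockwise
when viewed from the patient's front.  The second imager leads the first by
+90 degrees.  Detector ``u`` runs horizontally (perpendicular to SI),
``v`` runs vertically and increases toward patient-inferior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import (
    BehindSourceError,
    DegenerateEpipoleError,
    ParallelRaysError,
    PointAtSourceError,
)

__all__ = [
    "RoomPoint",
    "PixelCoord",
    "ViewGeometry",
    "Ray",
    "EpipolarSegment",
    "view_pair",
    "project_point",
    "backproject_ray",
    "triangulate",
    "epipolar_segment",
    "classify_region",
    "LATERAL_BANDS_DEG",
]

#: Gantry-angle bands (degrees, inclusive) in which the imaging view is
#: lateral and the two hemidiaphragm shadows may overlap.
LATERAL_BANDS_DEG = ((50.0, 130.0), (230.0, 310.0))

DEFAULT_SAD_MM = 1000.0
DEFAULT_SID_MM = 2000.0
DEFAULT_ISO_PIXEL_MM = 0.2
DEFAULT_WIDTH = 768
DEFAULT_HEIGHT = 1024


def _as_room(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("room point components must be finite")
    return a


@dataclass(frozen=True)
class RoomPoint:
    """3D position in the room frame, millimetres from the isocenter."""

    x_lr: float
    y_ap: float
    z_si: float

    def __post_init__(self):
        _as_room((self.x_lr, self.y_ap, self.z_si))

    @classmethod
    def from_array(cls, a) -> "RoomPoint":
        a = _as_room(a)
        return cls(float(a[0]), float(a[1]), float(a[2]))

    def to_array(self) -> np.ndarray:
        return np.array([self.x_lr, self.y_ap, self.z_si], dtype=float)


@dataclass(frozen=True)
class PixelCoord:
    """Continuous 0-based detector pixel; ``v`` increases toward inferior."""

    u: float
    v: float

    def __post_init__(self):
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    def to_array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class ViewGeometry:
    """Projection geometry of one kV imager at one gantry angle.

    ``detector_pitch`` is derived from the isocenter pixel size so that
    ``detector_pitch * SAD / SID == isocenter_pixel_size`` (0.2 mm default).
    """

    gantry_angle: float
    imager_index: int = 1
    sad: float = DEFAULT_SAD_MM
    sid: float = DEFAULT_SID_MM
    isocenter_pixel_size: float = DEFAULT_ISO_PIXEL_MM
    image_width: int = DEFAULT_WIDTH
    image_height: int = DEFAULT_HEIGHT
    principal_point: PixelCoord = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if not (self.sid > self.sad > 0):
            raise ValueError("require SID > SAD > 0")
        if self.imager_index not in (1, 2):
            raise ValueError("imager_index must be 1 or 2")
        if self.principal_point is None:
            object.__setattr__(
                self,
                "principal_point",
                PixelCoord((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0),
            )

    @property
    def detector_pitch(self) -> float:
        """Detector pixel pitch in mm/px."""
        return self.isocenter_pixel_size * self.sid / self.sad

    # -- basis vectors -------------------------------------------------------

    @property
    def source_direction(self) -> np.ndarray:
        """Unit vector from isocenter toward the source."""
        th = np.deg2rad(self.gantry_angle)
        return np.array([np.sin(th), np.cos(th), 0.0])

    @property
    def source_position(self) -> np.ndarray:
        return self.sad * self.source_direction

    @property
    def u_axis(self) -> np.ndarray:
        """Room direction of increasing detector u (horizontal)."""
        th = np.deg2rad(self.gantry_angle)
        return np.array([np.cos(th), -np.sin(th), 0.0])

    @property
    def v_axis(self) -> np.ndarray:
        """Room direction of increasing detector v (toward inferior)."""
        return np.array([0.0, 0.0, -1.0])

    @property
    def detector_center(self) -> np.ndarray:
        return self.source_position - self.sid * self.source_direction

    def detector_point(self, q: PixelCoord) -> np.ndarray:
        """Room-frame position of a detector pixel."""
        pitch = self.detector_pitch
        return (
            self.detector_center
            + (q.u - self.principal_point.u) * pitch * self.u_axis
            + (q.v - self.principal_point.v) * pitch * self.v_axis
        )

    def at_angle(self, gantry_angle: float) -> "ViewGeometry":
        return replace(self, gantry_angle=float(gantry_angle))


def view_pair(
    gantry_angle: float, imager_offset_deg: float = 90.0, **kwargs
) -> tuple[ViewGeometry, ViewGeometry]:
    """The two simultaneous views at one gantry position (imager 2 at +90 deg)."""
    g1 = ViewGeometry(gantry_angle=float(gantry_angle) % 360.0, imager_index=1, **kwargs)
    g2 = ViewGeometry(
        gantry_angle=(float(gantry_angle) + imager_offset_deg) % 360.0,
        imager_index=2,
        **kwargs,
    )
    return g1, g2


@dataclass(frozen=True)
class Ray:
    """Half-line from an x-ray source into the room."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = _as_room(self.origin)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("ray direction must be nonzero")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)

    def point_at(self, t: float) -> np.ndarray:
        return self.origin + t * self.direction

    def distance_to(self, p) -> float:
        """Perpendicular distance from a point to the infinite line."""
        w = _as_room(p) - self.origin
        return float(np.linalg.norm(w - np.dot(w, self.direction) * self.direction))


@dataclass(frozen=True)
class EpipolarSegment:
    """Epipolar line ``a*u + b*v + c = 0`` (a^2 + b^2 = 1) with its
    intersections with the image's left and right edges."""

    a: float
    b: float
    c: float
    edge_points: tuple[PixelCoord, PixelCoord]

    def signed_distance(self, q: PixelCoord) -> float:
        return self.a * q.u + self.b * q.v + self.c

    def v_at(self, u: float) -> float:
        if abs(self.b) < 1e-12:
            raise DegenerateEpipoleError("line is vertical; v(u) undefined")
        return -(self.c + self.a * u) / self.b


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def project_point(geom: ViewGeometry, p) -> PixelCoord:
    """Perspective-project a room point onto the detector, in pixels.

    Raises ``PointAtSourceError`` if *p* coincides with the source and
    ``BehindSourceError`` if *p* is on the far side of the source so the
    projection is undefined.
    """
    pa = p.to_array() if isinstance(p, RoomPoint) else _as_room(p)
    d = pa - geom.source_position
    if np.linalg.norm(d) < 1e-12:
        raise PointAtSourceError("point coincides with the x-ray source")
    depth = float(np.dot(d, -geom.source_direction))
    if depth <= 1e-12:
        raise BehindSourceError("point does not lie on the detector side of the source")
    scale = geom.sid / depth
    pitch = geom.detector_pitch
    u = geom.principal_point.u + float(np.dot(d, geom.u_axis)) * scale / pitch
    v = geom.principal_point.v + float(np.dot(d, geom.v_axis)) * scale / pitch
    return PixelCoord(u, v)


def backproject_ray(geom: ViewGeometry, q: PixelCoord) -> Ray:
    """Ray from the source through detector pixel *q*."""
    det = geom.detector_point(q)
    return Ray(origin=geom.source_position, direction=det - geom.source_position)


def triangulate(r1: Ray, r2: Ray) -> tuple[RoomPoint, float]:
    """Midpoint of the common perpendicular between two (infinite) rays.

    Returns the estimated 3D point and the length of the shortest segment
    connecting the rays (``0`` for exactly intersecting rays).  Raises
    ``ParallelRaysError`` for parallel directions.
    """
    d1, d2 = r1.direction, r2.direction
    cross = np.cross(d1, d2)
    if np.linalg.norm(cross) < 1e-12:
        raise ParallelRaysError("rays are parallel; no unique closest point")
    w0 = r1.origin - r2.origin
    a = np.dot(d1, d1)
    b = np.dot(d1, d2)
    c = np.dot(d2, d2)
    d = np.dot(d1, w0)
    e = np.dot(d2, w0)
    denom = a * c - b * b
    t1 = (b * e - c * d) / denom
    t2 = (a * e - b * d) / denom
    p1 = r1.point_at(t1)
    p2 = r2.point_at(t2)
    midpoint = 0.5 * (p1 + p2)
    residual = float(np.linalg.norm(p1 - p2))
    return RoomPoint.from_array(midpoint), residual


def epipolar_segment(
    geom_src: ViewGeometry, q_src: PixelCoord, geom_dst: ViewGeometry
) -> EpipolarSegment:
    """Project the back-projected ray of *q_src* into *geom_dst*.

    The two sampled ray points straddle the isocenter depth so the
    projected chord is well conditioned.  Raises ``DegenerateEpipoleError``
    if the ray maps to (numerically) a single point, or if the resulting
    line is vertical and so never crosses both left and right image edges.
    """
    ray = backproject_ray(geom_src, q_src)
    # sample depths below 0.8*SAD: for orthogonal views such points always
    # stay on the source side of the destination imager
    qa = project_point(geom_dst, ray.point_at(0.4 * geom_src.sad))
    qb = project_point(geom_dst, ray.point_at(0.8 * geom_src.sad))
    du = qb.u - qa.u
    dv = qb.v - qa.v
    norm = float(np.hypot(du, dv))
    if norm < 1e-9:
        raise DegenerateEpipoleError("ray projects to a single point in this view")
    # line through (qa, qb): normal is the rotated chord direction
    a = dv / norm
    b = -du / norm
    c = -(a * qa.u + b * qa.v)
    if abs(b) < 1e-12:
        raise DegenerateEpipoleError("epipolar line is vertical; no edge crossings")
    u_left, u_right = 0.0, float(geom_dst.image_width - 1)
    left = PixelCoord(u_left, -(c + a * u_left) / b)
    right = PixelCoord(u_right, -(c + a * u_right) / b)
    return EpipolarSegment(a=a, b=b, c=c, edge_points=(left, right))


def classify_region(gantry_angle: float) -> str:
    """``"lateral"`` iff the angle falls in 50-130 or 230-310 deg (inclusive)."""
    ang = float(gantry_angle) % 360.0
    for lo, hi in LATERAL_BANDS_DEG:
        if lo <= ang <= hi:
            return "lateral"
    return "non_lateral"
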