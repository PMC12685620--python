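"""kV-frame preprocessing and epipolar-constrained template matching.

The preprocessing chain mirrors the acquisition side: fiducial shadows are
inpainted from an annular neighborhood, intensities are log-compressed and
polarity-inverted so dense structures appear bright, and the frame is
passed through a downsample/restore cycle that suppresses detail below the
template resolution.  Diaphragm detection is exhaustive zero-mean
normalized cross-correlation of an angle-indexed template inside a small
search window anchored on the previous frame (non-lateral views) or on the
epipolar line of the paired view's detection (lateral views).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.feature import match_template
from skimage.transform import resize, resize_local_mean

from .exceptions import (
    BadDimsError,
    EmptyWindowError,
    LostTrackError,
    MissingEpipolarError,
    ZeroVarianceError,
)
from .geometry import (
    EpipolarSegment,
    PixelCoord,
    ViewGeometry,
    backproject_ray,
    classify_region,
    epipolar_segment,
    triangulate,
)

__all__ = [
    "ProjectionImage",
    "DiaphragmTemplate",
    "MatchResult",
    "SearchWindow",
    "TrackResult",
    "TEMPLATE_SHAPE",
    "TEMPLATE_APEX_OFFSET",
    "inpaint_markers",
    "log_invert",
    "resolution_match",
    "preprocess",
    "ncc_match",
    "seed_match",
    "build_search_window",
    "nearest_template",
    "track_session",
]

TEMPLATE_SHAPE = (199, 299)  # rows (v) x cols (u)
TEMPLATE_APEX_OFFSET = PixelCoord(149.0, 99.0)  # template center, (u, v)

DOWNSAMPLE_SHAPE = (205, 75)  # rows (v) x cols (u)

INPAINT_RADIUS_PX = 5.0
ANNULUS_OUTER_PX = 10.0

SEARCH_DU_PX = 10
SEARCH_DV_PX = 50
EPIPOLAR_MARGIN_PX = 15

GAMMA_FLOOR_DEFAULT = 0.2
LOST_TRACK_FRAMES = 5


@dataclass
class ProjectionImage:
    """One detector frame: intensities (rows = v, cols = u) plus metadata."""

    intensity: np.ndarray
    time_s: float = 0.0
    view: ViewGeometry | None = None
    known_marker_pixels: tuple[PixelCoord, ...] = ()

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise BadDimsError("intensity must be a 2D array")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be nonnegative")
        if self.view is not None and self.intensity.shape != (
            self.view.image_height,
            self.view.image_width,
        ):
            raise BadDimsError("intensity shape does not match the view geometry")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensity.shape


@dataclass
class DiaphragmTemplate:
    """Apex-centered template tied to one 0.3-degree grid gantry angle."""

    intensity: np.ndarray
    gantry_angle: float
    apex_offset: PixelCoord = TEMPLATE_APEX_OFFSET
    strict_shape: bool = True  # disable for reduced-size templates in tests

    def __post_init__(self):
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.strict_shape and self.intensity.shape != TEMPLATE_SHAPE:
            raise BadDimsError(
                f"template must be {TEMPLATE_SHAPE}, got {self.intensity.shape}"
            )


@dataclass(frozen=True)
class SearchWindow:
    """Inclusive bounds on the candidate apex pixel."""

    u_min: int
    u_max: int
    v_min: int
    v_max: int

    def __post_init__(self):
        if self.u_min > self.u_max or self.v_min > self.v_max:
            raise EmptyWindowError(f"empty search window {self}")

    def contains(self, q: PixelCoord) -> bool:
        return self.u_min <= q.u <= self.u_max and self.v_min <= q.v <= self.v_max

    @property
    def size(self) -> tuple[int, int]:
        return (self.u_max - self.u_min + 1, self.v_max - self.v_min + 1)


@dataclass(frozen=True)
class MatchResult:
    apex: PixelCoord
    gamma: float
    search_window: SearchWindow
    region: str

    def __post_init__(self):
        if not -1.0 <= self.gamma <= 1.0:
            raise ValueError("gamma outside [-1, 1]")
        if not self.search_window.contains(self.apex):
            raise ValueError("apex outside its search window")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def _disk_masks(shape, center: PixelCoord):
    vv, uu = np.ogrid[: shape[0], : shape[1]]
    r2 = (uu - center.u) ** 2 + (vv - center.v) ** 2
    disc = r2 <= INPAINT_RADIUS_PX**2
    annulus = (r2 > INPAINT_RADIUS_PX**2) & (r2 <= ANNULUS_OUTER_PX**2)
    return disc, annulus


def inpaint_markers(img: ProjectionImage) -> ProjectionImage:
    """Replace each 5-px marker disc with its 5-10 px annulus mean.

    Markers near the border use the in-image part of the annulus; pixels
    outside every disc are untouched.
    """
    if not img.known_marker_pixels:
        return replace(img, intensity=img.intensity.copy())
    out = img.intensity.copy()
    for c in img.known_marker_pixels:
        disc, annulus = _disk_masks(out.shape, c)
        if annulus.any():
            out[disc] = img.intensity[annulus].mean()
    return replace(img, intensity=out)


def log_invert(img: ProjectionImage) -> ProjectionImage:
    """Log-compress then flip polarity; rescale to the input dynamic range."""
    x = img.intensity
    lo, hi = float(x.min()), float(x.max())
    logged = np.log1p(x)
    inv = logged.max() - logged
    span = float(inv.max() - inv.min())
    if span == 0.0 or hi == lo:  # constant image maps to itself
        return replace(img, intensity=x.copy())
    out = lo + (inv - inv.min()) / span * (hi - lo)
    return replace(img, intensity=out)


def resolution_match(img: ProjectionImage) -> ProjectionImage:
    """Block-average down to 75x205 (u x v), restore by bilinear resize."""
    if img.shape != (1024, 768):
        raise BadDimsError(f"expected 1024x768 frame, got {img.shape}")
    small = resize_local_mean(img.intensity, DOWNSAMPLE_SHAPE)
    restored = resize(small, img.shape, order=1, anti_aliasing=False)
    return replace(img, intensity=np.clip(restored, 0.0, None))


def preprocess(img: ProjectionImage) -> ProjectionImage:
    """Full chain: inpaint markers, log-invert, resolution match."""
    return resolution_match(log_invert(inpaint_markers(img)))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------


def _placement_bounds(img_shape, tmpl: DiaphragmTemplate):
    """Inclusive apex-pixel bounds keeping the template fully in the image."""
    th, tw = tmpl.intensity.shape
    ou, ov = int(tmpl.apex_offset.u), int(tmpl.apex_offset.v)
    return ou, img_shape[1] - (tw - ou), ov, img_shape[0] - (th - ov)


def ncc_match(
    img: ProjectionImage, tmpl: DiaphragmTemplate, window: SearchWindow, region: str = "non_lateral"
) -> MatchResult:
    """Exhaustive zero-mean NCC over integer apex placements in *window*.

    Ties are broken toward the smallest v, then smallest u.  Raises
    ``EmptyWindowError`` when no placement keeps the template inside the
    image and ``ZeroVarianceError`` when the correlation is undefined
    everywhere (constant template or all-constant patches).
    """
    th, tw = tmpl.intensity.shape
    ou, ov = int(tmpl.apex_offset.u), int(tmpl.apex_offset.v)
    lo_u, hi_u, lo_v, hi_v = _placement_bounds(img.shape, tmpl)
    u0, u1 = max(window.u_min, lo_u), min(window.u_max, hi_u)
    v0, v1 = max(window.v_min, lo_v), min(window.v_max, hi_v)
    if u0 > u1 or v0 > v1:
        raise EmptyWindowError("no valid template placement inside the window")

    t0 = tmpl.intensity - tmpl.intensity.mean()
    t_ss = float(np.sum(t0 * t0))
    if t_ss <= 0.0:
        raise ZeroVarianceError("constant template")

    crop = np.ascontiguousarray(
        img.intensity[v0 - ov : v1 - ov + th, u0 - ou : u1 - ou + tw]
    )
    nv, nu = v1 - v0 + 1, u1 - u0 + 1
    n_px = th * tw
    t_flat = t0.ravel()
    cross = np.empty((nv, nu))
    s1 = np.empty((nv, nu))
    s2 = np.empty((nv, nu))
    # exhaustive over every placement; row-chunked so each chunk of patches
    # is a dense (nu, th*tw) matrix and the sums run through BLAS
    for iv in range(nv):
        w = sliding_window_view(crop[iv : iv + th, :], (th, tw))
        w = w.reshape(nu, n_px)
        cross[iv] = w @ t_flat
        s1[iv] = w.sum(axis=1)
        s2[iv] = np.einsum("ij,ij->i", w, w)
    var = s2 - s1 * s1 / n_px
    valid = var > 1e-12 * n_px
    if not valid.any():
        raise ZeroVarianceError("every candidate patch is constant")
    gamma = np.full(var.shape, -np.inf)
    gamma[valid] = cross[valid] / np.sqrt(t_ss * var[valid])
    flat = int(np.argmax(gamma))  # row-major: smallest v, then smallest u
    iv, iu = np.unravel_index(flat, gamma.shape)
    g = float(np.clip(gamma[iv, iu], -1.0, 1.0))
    return MatchResult(
        apex=PixelCoord(float(u0 + iu), float(v0 + iv)),
        gamma=g,
        search_window=window,
        region=region,
    )


def seed_match(img: ProjectionImage, tmpl: DiaphragmTemplate, refine_px: int = 4) -> MatchResult:
    """Whole-image first-frame seeding.

    An FFT correlation pass proposes a location, which is then verified by
    the exhaustive matcher in a small window around it.
    """
    th, tw = tmpl.intensity.shape
    ou, ov = int(tmpl.apex_offset.u), int(tmpl.apex_offset.v)
    corr = match_template(img.intensity, tmpl.intensity)
    iv, iu = np.unravel_index(int(np.argmax(corr)), corr.shape)
    lo_u, hi_u, lo_v, hi_v = _placement_bounds(img.shape, tmpl)
    window = SearchWindow(
        max(iu + ou - refine_px, lo_u),
        min(iu + ou + refine_px, hi_u),
        max(iv + ov - refine_px, lo_v),
        min(iv + ov + refine_px, hi_v),
    )
    return ncc_match(img, tmpl, window)


def build_search_window(
    prev_apex: PixelCoord,
    region: str,
    epi: EpipolarSegment | None,
    geom: ViewGeometry,
    du: int = SEARCH_DU_PX,
    dv: int = SEARCH_DV_PX,
    epi_margin: int = EPIPOLAR_MARGIN_PX,
) -> SearchWindow:
    """Search window around the previous apex, clipped to the image.

    Non-lateral: ``u`` within +/-10 px of the previous apex, ``v`` within
    +/-50 px.  Lateral: same ``u`` rule, but ``v`` spans the epipolar
    line's left/right edge intersections widened by 15 px.
    """
    xp, yp = int(round(prev_apex.u)), int(round(prev_apex.v))
    u_min, u_max = xp - du, xp + du
    if region == "lateral":
        if epi is None:
            raise MissingEpipolarError("lateral-region window requires an epipolar line")
        v_edges = (epi.edge_points[0].v, epi.edge_points[1].v)
        v_min = int(np.floor(min(v_edges))) - epi_margin
        v_max = int(np.ceil(max(v_edges))) + epi_margin
    else:
        v_min, v_max = yp - dv, yp + dv
    u_min = max(u_min, 0)
    v_min = max(v_min, 0)
    u_max = min(u_max, geom.image_width - 1)
    v_max = min(v_max, geom.image_height - 1)
    return SearchWindow(u_min, u_max, v_min, v_max)


def nearest_template(
    templates: list[DiaphragmTemplate], gantry_angle: float
) -> DiaphragmTemplate:
    """Template whose grid angle is circularly nearest; ties to the lower angle."""
    angles = np.array([t.gantry_angle for t in templates])
    diff = np.abs((angles - gantry_angle + 180.0) % 360.0 - 180.0)
    best = np.flatnonzero(diff == diff.min())
    if best.size > 1:
        best = best[np.argsort(angles[best])]
    return templates[int(best[0])]


@dataclass
class TrackResult:
    """Per-frame detections of one dual-view tracking run."""

    times_s: np.ndarray
    matches: dict[int, list[MatchResult]]  # imager -> per-frame results
    apex_3d: np.ndarray  # (n, 3) room mm
    residual_mm: np.ndarray  # (n,) triangulation skew residuals

    def apex_2d(self, imager: int) -> np.ndarray:
        return np.array([[m.apex.u, m.apex.v] for m in self.matches[imager]])

    def gammas(self, imager: int) -> np.ndarray:
        return np.array([m.gamma for m in self.matches[imager]])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for imager, results in sorted(self.matches.items()):
            for t, m in zip(self.times_s, results):
                rows.append(
                    {
                        "time_s": t,
                        "imager": imager,
                        "u_px": m.apex.u,
                        "v_px": m.apex.v,
                        "gamma": m.gamma,
                        "region": m.region,
                    }
                )
        return pd.DataFrame(rows)


def track_session(
    frames: dict[int, list[ProjectionImage]],
    templates: dict[int, list[DiaphragmTemplate]],
    initial_apexes: dict[int, PixelCoord] | None = None,
    times_s: np.ndarray | None = None,
    gamma_floor: float = GAMMA_FLOOR_DEFAULT,
    preprocessed: bool = False,
) -> TrackResult:
    """Track the diaphragm apex through a dual-view session.

    Per frame: classify each view; detect in non-lateral views first using
    the previous-frame window; constrain any lateral view by the epipolar
    line of the paired detection; triangulate the two 2D apexes into a 3D
    apex.  Frames must carry their ``view`` geometry.  If *initial_apexes*
    is omitted the first frame is seeded by a whole-image match.

    Raises ``LostTrackError`` if a view's score stays below *gamma_floor*
    for 5 consecutive frames.
    """
    imagers = sorted(frames)
    if len(imagers) != 2:
        raise ValueError("track_session expects exactly two imagers")
    n = len(frames[imagers[0]])
    if any(len(frames[i]) != n for i in imagers):
        raise ValueError("imagers must have the same number of frames")
    if times_s is None:
        times_s = np.array([frames[imagers[0]][k].time_s for k in range(n)])

    prev: dict[int, PixelCoord] = {}
    low_streak = {i: 0 for i in imagers}
    matches: dict[int, list[MatchResult]] = {i: [] for i in imagers}
    apex_3d = np.zeros((n, 3))
    residual = np.zeros(n)

    for k in range(n):
        imgs = {}
        for i in imagers:
            f = frames[i][k]
            if f.view is None:
                raise ValueError("frames must carry their view geometry")
            imgs[i] = f if preprocessed else preprocess(f)
        regions = {i: classify_region(imgs[i].view.gantry_angle) for i in imagers}
        order = sorted(imagers, key=lambda i: regions[i] == "lateral")

        frame_matches: dict[int, MatchResult] = {}
        for i in order:
            img = imgs[i]
            tmpl = nearest_template(templates[i], img.view.gantry_angle)
            if k == 0 and (initial_apexes is None or i not in initial_apexes):
                frame_matches[i] = seed_match(img, tmpl)
            else:
                anchor = prev[i] if k > 0 else initial_apexes[i]
                epi = None
                if regions[i] == "lateral":
                    j = order[0]  # the non-lateral (or first) partner view
                    epi = epipolar_segment(
                        imgs[j].view, frame_matches[j].apex, img.view
                    )
                window = build_search_window(anchor, regions[i], epi, img.view)
                frame_matches[i] = ncc_match(img, tmpl, window, region=regions[i])
            m = frame_matches[i]
            low_streak[i] = low_streak[i] + 1 if m.gamma < gamma_floor else 0
            if low_streak[i] >= LOST_TRACK_FRAMES:
                raise LostTrackError(
                    f"imager {i}: gamma < {gamma_floor} for "
                    f"{LOST_TRACK_FRAMES} consecutive frames ending at frame {k}"
                )
            matches[i].append(m)
            prev[i] = m.apex

        i1, i2 = imagers
        r1 = backproject_ray(imgs[i1].view, frame_matches[i1].apex)
        r2 = backproject_ray(imgs[i2].view, frame_matches[i2].apex)
        pt, res = triangulate(r1, r2)
        apex_3d[k] = pt.to_array()
        residual[k] = res

    return TrackResult(
        times_s=np.asarray(times_s, dtype=float),
        matches=matches,
        apex_3d=apex_3d,
        residual_mm=residual,
    )
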