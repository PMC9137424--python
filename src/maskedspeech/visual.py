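"""Simulated visual face masks: landmark polygons and frame rendering.

A mask is drawn as filled white polygons anchored to per-frame facial
landmarks.  The canonical 66-point layout used throughout this package is:

====== ======================================
index  region
====== ======================================
0-16   lower-face perimeter (jaw line), left to right
17-26  eyebrows (5 per brow)
27-30  nose bridge, top to bottom (27 = top middle)
31-35  nostril base
36-47  eyes (6 per eye)
48-65  lips: 12 outer-rim + 6 inner-rim points
====== ======================================

Opaque masks (hospital, fabric) are a single polygon through the 17 jaw
points closed via the top nose-bridge point.  The windowed mask
(Communicator-style) uses the same outer shape with a rectangular cutout
over the lips, dilated by a configurable fraction of mouth width.  A fully
transparent mask (ClearMask-style) draws nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import Point
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "N_LANDMARKS",
    "LANDMARK_GROUPS",
    "LandmarkFrame",
    "MaskShapeSpec",
    "MaskPolygon",
    "build_mask_polygons",
    "render_mask",
    "occlusion_report",
]

N_LANDMARKS = 66

#: Landmark index ranges per facial region.
LANDMARK_GROUPS: dict[str, range] = {
    "jaw": range(0, 17),
    "brows": range(17, 27),
    "nose": range(27, 36),
    "eyes": range(36, 48),
    "lips": range(48, 66),
}

_JAW = LANDMARK_GROUPS["jaw"]
_LIPS = LANDMARK_GROUPS["lips"]
_NOSE_BRIDGE_TOP = 27


@dataclass
class LandmarkFrame:
    """One frame of 66 (x, y) pixel coordinates in the canonical layout."""

    frame_index: int
    points: np.ndarray
    frame_size: tuple[int, int] | None = None  # (width, height)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} (x, y) landmarks, got array of shape "
                f"{self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates contain non-finite values")
        if self.frame_size is not None:
            w, h = self.frame_size
            x, y = self.points[:, 0], self.points[:, 1]
            if x.min() < 0 or y.min() < 0 or x.max() >= w or y.max() >= h:
                raise ValueError("landmark coordinates fall outside frame bounds")
        perimeter = _ShapelyPolygon(self._outer_ring())
        for i in _LIPS:
            if not perimeter.covers(Point(self.points[i])):
                raise ValueError(
                    f"lip landmark {i} lies outside the lower-face perimeter"
                )

    def _outer_ring(self) -> np.ndarray:
        """Jaw points 0-16 closed through the top nose-bridge point (18 vertices)."""
        return np.vstack([self.points[list(_JAW)], self.points[_NOSE_BRIDGE_TOP]])

    @property
    def lips(self) -> np.ndarray:
        return self.points[list(_LIPS)]


@dataclass(frozen=True)
class MaskShapeSpec:
    """Which mask to draw.

    kind
        ``"none"`` (no overlay, transparent mask), ``"opaque"`` (hospital /
        fabric) or ``"windowed"`` (opaque with a transparent mouth cutout).
    window_margin
        Cutout dilation as a fraction of mouth width (windowed only).
    fill
        RGB fill color; pure white by default, hard edges.
    """

    kind: str = "opaque"
    window_margin: float = 0.2
    fill: tuple[int, int, int] = (255, 255, 255)

    def __post_init__(self) -> None:
        if self.kind not in ("none", "opaque", "windowed"):
            raise ValueError(f"unknown mask kind {self.kind!r}")
        if self.window_margin < 0:
            raise ValueError("window_margin must be >= 0")


@dataclass
class MaskPolygon:
    """A filled polygon with optional holes (rings of (x, y) vertices)."""

    exterior: np.ndarray
    holes: list[np.ndarray] = field(default_factory=list)

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.exterior, [h for h in self.holes])


def build_mask_polygons(lm: LandmarkFrame, spec: MaskShapeSpec) -> list[MaskPolygon]:
    """Mask polygons for one frame.

    * ``none``: empty list.
    * ``opaque``: one 18-vertex polygon (jaw line + top nose-bridge point).
    * ``windowed``: the same outer polygon with a hole equal to the
      axis-aligned bounding box of the 18 lip points, dilated on every side
      by ``window_margin`` times the mouth width.
    """
    lm.validate()
    if spec.kind == "none":
        return []
    outer = lm._outer_ring()
    if spec.kind == "opaque":
        return [MaskPolygon(outer)]
    lips = lm.lips
    x0, y0 = lips.min(axis=0)
    x1, y1 = lips.max(axis=0)
    margin = spec.window_margin * (x1 - x0)
    x0, x1 = x0 - margin, x1 + margin
    y0, y1 = y0 - margin, y1 + margin
    hole = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    return [MaskPolygon(outer, holes=[hole])]


def render_mask(
    frame: np.ndarray | Image.Image,
    polygons: list[MaskPolygon],
    fill: tuple[int, int, int] = (255, 255, 255),
) -> np.ndarray:
    """Superimpose filled polygons onto a frame.

    Pixels inside a polygon (holes excluded) are set to ``fill``; all other
    pixels are byte-identical to the input.  No anti-aliasing, so rendering
    is idempotent and bit-exact.
    """
    arr = np.array(frame) if isinstance(frame, Image.Image) else np.asarray(frame).copy()
    if not polygons:
        return arr
    h, w = arr.shape[:2]
    stencil = Image.new("1", (w, h), 0)
    draw = ImageDraw.Draw(stencil)
    for poly in polygons:
        draw.polygon([tuple(p) for p in np.round(poly.exterior).astype(int)], fill=1)
        for hole in poly.holes:
            draw.polygon([tuple(p) for p in np.round(hole).astype(int)], fill=0)
    mask = np.array(stencil, dtype=bool)
    if arr.ndim == 2:
        arr[mask] = fill[0]
    else:
        arr[mask] = np.asarray(fill[: arr.shape[2]], dtype=arr.dtype)
    return arr


def occlusion_report(
    lm: LandmarkFrame, polygons: list[MaskPolygon]
) -> dict[str, float]:
    """Fraction of landmarks covered by the mask, per facial region.

    Containment is inclusive of the mask outline (the jaw landmarks lie
    exactly on it); points inside a cutout window count as visible.
    """
    shapes = [p.to_shapely() for p in polygons]
    report = {}
    for group, idx in LANDMARK_GROUPS.items():
        pts = [Point(lm.points[i]) for i in idx]
        covered = sum(any(s.covers(pt) for s in shapes) for pt in pts)
        report[group] = covered / len(pts)
    return report
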