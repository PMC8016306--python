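"""Gross contact area from ink-stamped fingerprint images.

The ink method stamps the inked finger pad on white paper next to a 5.0 cm
reference bar.  Quantification proceeds in four steps: (1) scale pixels
from the reference bar, (2) threshold ink-colored pixels inside an
analyst-chosen circular region of interest, (3) trace the exterior outline
of the dominant connected component, and (4) evaluate Gauss's (shoelace)
formula on the outline in squared centimeters.

The outline is traced along pixel edges (crack following, a serial
boundary search), so its shoelace area equals the enclosed pixel count
exactly; interior holes are not subtracted because the measurement is
defined on the exterior outline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from shapely.geometry import Polygon as _ShapelyPolygon
from skimage.color import rgb2hsv
from skimage.measure import label
from skimage.morphology import closing, disk, opening

__all__ = [
    "InkImage",
    "InkThreshold",
    "ContactOutline",
    "pixel_scale",
    "detect_bar_pixels",
    "threshold_contact_region",
    "trace_outline",
    "polygon_area",
    "measure_contact_area",
    "load_ink_image",
]

DEFAULT_BAR_LENGTH_CM = 5.0


@dataclass
class InkImage:
    """A digitized ink stamp with its reference-bar annotation."""

    raster: np.ndarray  # (H, W, 3) RGB
    bar_pixels: float | None = None
    bar_length: float = DEFAULT_BAR_LENGTH_CM  # cm

    def __post_init__(self):
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 3 or self.raster.shape[2] < 3 or self.raster.size == 0:
            raise ValueError("raster must be a non-empty RGB pixel grid")


@dataclass(frozen=True)
class InkThreshold:
    """HSV bounds classifying a pixel as ink.

    A pixel is ink when its saturation is at least ``s_min`` OR its value
    (brightness) is at most ``v_max``; white paper background fails both.
    """

    s_min: float = 0.25
    v_max: float = 0.55


@dataclass(frozen=True)
class ContactOutline:
    """Ordered outline polygon (pixel coordinates, (x, y)) and its scale."""

    polygon: np.ndarray  # (n, 2) vertices along pixel edges
    scale: float  # cm per pixel

    def __post_init__(self):
        object.__setattr__(self, "polygon", np.asarray(self.polygon, dtype=float))
        if self.polygon.shape[0] < 3:
            raise ValueError("outline needs at least 3 vertices")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def pixel_scale(image: InkImage) -> float:
    """Physical scale (cm per pixel) from the reference bar.

    Uses the annotated bar length in pixels; falls back to automatic bar
    detection when no annotation is present.
    """
    bar_px = image.bar_pixels
    if bar_px is None:
        bar_px = detect_bar_pixels(image.raster)
    if bar_px is None or bar_px <= 0:
        raise ValueError("reference bar length in pixels is missing or non-positive")
    return image.bar_length / float(bar_px)


def detect_bar_pixels(raster: np.ndarray, v_max: float = 0.35) -> float | None:
    """Detect the reference bar as the longest dark horizontal pixel run."""
    hsv = rgb2hsv(np.asarray(raster)[..., :3])
    dark = hsv[..., 2] <= v_max
    best = 0
    for row in dark:
        run = 0
        for flag in row:
            run = run + 1 if flag else 0
            best = max(best, run)
    return float(best) if best > 1 else None


def threshold_contact_region(
    image: InkImage,
    roi_center: tuple[float, float],
    roi_radius: float,
    color_threshold: InkThreshold | None = None,
    clean: bool = True,
) -> np.ndarray:
    """Binary ink mask inside a circular region of interest.

    ``roi_center`` is (x, y) in pixel coordinates; everything outside the
    ROI disk is masked out (which also excludes the reference bar).  A
    small morphological opening/closing removes speckle noise and pinholes.
    Returns an all-false mask (with a warning) when no ink is found.
    """
    thr = color_threshold or InkThreshold()
    h, w = image.raster.shape[:2]
    cx, cy = roi_center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("ROI center lies outside the raster")
    hsv = rgb2hsv(image.raster[..., :3])
    ink = (hsv[..., 1] >= thr.s_min) | (hsv[..., 2] <= thr.v_max)
    yy, xx = np.mgrid[0:h, 0:w]
    roi = (xx - cx) ** 2 + (yy - cy) ** 2 <= roi_radius**2
    mask = ink & roi
    if clean and mask.any():
        mask = opening(mask, disk(1))
        mask = closing(mask, disk(2))
        mask &= roi
    if not mask.any():
        warnings.warn("no ink pixels found inside ROI; contact area is 0", stacklevel=2)
    return mask


_MOVES = {"E": (0, 1), "S": (1, 0), "W": (0, -1), "N": (-1, 0)}
_RIGHT_OF = {"E": "S", "S": "W", "W": "N", "N": "E"}
_LEFT_OF = {v: k for k, v in _RIGHT_OF.items()}
# pixel on the right / left of a move leaving corner (r, c)
_SIDE_PIXELS = {
    "E": (lambda r, c: (r, c), lambda r, c: (r - 1, c)),
    "W": (lambda r, c: (r - 1, c - 1), lambda r, c: (r, c - 1)),
    "S": (lambda r, c: (r, c - 1), lambda r, c: (r, c)),
    "N": (lambda r, c: (r - 1, c), lambda r, c: (r - 1, c - 1)),
}


def _trace_crack_boundary(mask: np.ndarray) -> np.ndarray:
    """Exterior boundary of a mask along pixel edges (inside kept on the right).

    Returns corner vertices (x, y); the shoelace area of the polygon equals
    the number of enclosed pixels.
    """
    rows, cols = np.nonzero(mask)
    start_pixel = (int(rows.min()), int(cols[rows == rows.min()].min()))
    h, w = mask.shape

    def inside(rc):
        r, c = rc
        return 0 <= r < h and 0 <= c < w and bool(mask[r, c])

    def valid(corner, direction):
        right, left = _SIDE_PIXELS[direction]
        return inside(right(*corner)) and not inside(left(*corner))

    start = start_pixel  # top-left corner of the topmost-leftmost pixel
    direction = "E"
    assert valid(start, direction)
    corners = [start]
    corner, d = start, direction
    while True:
        dr, dc = _MOVES[d]
        corner = (corner[0] + dr, corner[1] + dc)
        if corner == start:
            break
        for cand in (_RIGHT_OF[d], d, _LEFT_OF[d], _RIGHT_OF[_RIGHT_OF[d]]):
            if valid(corner, cand):
                d = cand
                break
        else:  # pragma: no cover - cannot happen on a non-empty mask
            raise RuntimeError("boundary trace stalled")
        corners.append(corner)
    pts = np.array(corners, dtype=float)
    # drop collinear vertices
    keep = []
    n = len(pts)
    for i in range(n):
        a, b, c = pts[i - 1], pts[i], pts[(i + 1) % n]
        u, v = b - a, c - b
        if u[0] * v[1] - u[1] * v[0] != 0:
            keep.append(i)
    pts = pts[keep] if keep else pts
    return pts[:, ::-1]  # (row, col) -> (x, y)


def trace_outline(mask: np.ndarray, scale: float = 1.0) -> ContactOutline:
    """Exterior outline of the largest connected ink component.

    Multiple components trigger a warning and only the largest is traced.

    Raises
    ------
    ValueError
        If the mask is empty.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an outline of an empty mask")
    labels, n_comp = label(mask, connectivity=1, return_num=True)
    if n_comp > 1:
        warnings.warn(f"{n_comp} ink components found; tracing the largest", stacklevel=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    return ContactOutline(polygon=_trace_crack_boundary(mask), scale=scale)


def polygon_area(outline: ContactOutline) -> float:
    """Contact area (cm^2) of a simple polygon via Gauss's formula.

    ``|sum_i (x_i * y_{i+1} - x_{i+1} * y_i)| / 2 * scale^2``; invariant to
    the starting vertex and to orientation.

    Raises
    ------
    ValueError
        If the polygon has fewer than 3 vertices or self-intersects.
    """
    pts = outline.polygon
    if not _ShapelyPolygon(pts).is_valid:
        raise ValueError("outline polygon is self-intersecting")
    x, y = pts[:, 0], pts[:, 1]
    shoelace = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    return float(abs(shoelace) / 2.0 * outline.scale**2)


def measure_contact_area(
    image: InkImage,
    roi_center: tuple[float, float],
    roi_radius: float,
    color_threshold: InkThreshold | None = None,
) -> float:
    """End-to-end ink-method area (cm^2) for one stamped image.

    Returns 0.0 when no ink is detected inside the ROI.
    """
    scale = pixel_scale(image)
    mask = threshold_contact_region(image, roi_center, roi_radius, color_threshold)
    if not mask.any():
        return 0.0
    outline = trace_outline(mask, scale=scale)
    return polygon_area(outline)


def load_ink_image(path: str | Path) -> tuple[InkImage, dict]:
    """Load a PNG/TIFF stamp and its sidecar JSON annotation.

    The sidecar ``<stem>.json`` carries ``bar_pixels`` and the analyst ROI
    (``roi_center`` [x, y] and ``roi_radius``); it is returned alongside
    the image so callers can pass the ROI on.
    """
    path = Path(path)
    raster = np.asarray(Image.open(path).convert("RGB"))
    sidecar_path = path.with_suffix(".json")
    sidecar: dict = {}
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
    image = InkImage(
        raster=raster,
        bar_pixels=sidecar.get("bar_pixels"),
        bar_length=sidecar.get("bar_length_cm", DEFAULT_BAR_LENGTH_CM),
    )
    return image, sidecar
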