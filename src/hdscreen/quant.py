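"""Colony quantification from plate photographs.

Implements the measurement procedure of the screen: estimate the colony
grid (top-left colony position, row angle, pitch), then for every grid
position find the colony center as the intensity center of gravity in a
17x17 window, walk outward in the four cardinal directions to the first
background pixel (twice, re-centering in between), build an oval from the
four border distances, and score the colony as integrated density =
mean density x area, with area = pi * a * b.

"Background intensity" is modelled per plate as the median of pixels in
the inter-colony margins plus ``k`` robust spreads (k = 3 by default);
a pixel is background iff its intensity is at or below that threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

_FORMATS = {384: (16, 24), 1536: (32, 48)}


class GridDetectionError(RuntimeError):
    """No periodic colony structure could be found in the image."""


@dataclass
class GridSpec:
    """Geometry of a colony grid on a plate image.

    Coordinates are 0-based pixel indices, ``(x=col, y=row)``, top-left
    origin. ``angle`` is the rotation of colony rows relative to the image
    frame, in degrees.
    """

    n_rows: int
    n_cols: int
    top_left: tuple
    angle: float = 0.0
    pitch_x: float = 20.0
    pitch_y: float = 20.0

    def __post_init__(self) -> None:
        if self.pitch_x <= 0 or self.pitch_y <= 0:
            raise ValueError("pitch must be > 0")
        if self.n_rows * self.n_cols not in _FORMATS:
            raise ValueError("n_rows * n_cols must be 384 or 1536")
        if not -45.0 < self.angle < 45.0:
            raise ValueError("angle must lie in (-45, 45) degrees")

    @property
    def plate_format(self) -> int:
        return self.n_rows * self.n_cols


def grid_centers(grid: GridSpec) -> np.ndarray:
    """Predicted colony centers, shape (n_rows, n_cols, 2) as (x, y)."""
    th = math.radians(grid.angle)
    u = np.array([math.cos(th), math.sin(th)])  # along a row (col direction)
    v = np.array([-math.sin(th), math.cos(th)])  # along a column
    rows = np.arange(grid.n_rows)[:, None, None]
    cols = np.arange(grid.n_cols)[None, :, None]
    tl = np.asarray(grid.top_left, dtype=float)
    return tl + cols * grid.pitch_x * u + rows * grid.pitch_y * v


@dataclass
class BackgroundModel:
    """Background level and robust spread; cut at ``level + k * spread``.

    ``min_contrast`` (default half a gray level of an integer-valued image)
    floors the cut above the level so that, on a noiseless plate where the
    spread collapses to zero, vanishing colony tails are still background.
    """

    level: float
    spread: float = 0.0
    k: float = 3.0
    min_contrast: float = 0.5

    def __post_init__(self) -> None:
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if self.k <= 0:
            raise ValueError("k must be > 0")

    @property
    def threshold(self) -> float:
        return self.level + max(self.k * self.spread, self.min_contrast)

    def is_background(self, value) -> np.ndarray:
        return np.asarray(value) <= self.threshold


@dataclass
class ColonyMeasurement:
    row: int
    col: int
    center: tuple
    semi_axis_x: float
    semi_axis_y: float
    area: float
    mean_density: float
    integrated_density: float
    missing: bool = False
    flagged: bool = False


def _global_background(image: np.ndarray) -> BackgroundModel:
    level = float(np.median(image))
    spread = 1.4826 * float(np.median(np.abs(image - level)))
    return BackgroundModel(level=level, spread=spread)


def _foreground_centroids(image: np.ndarray, bg: BackgroundModel) -> np.ndarray:
    mask = image > bg.threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return np.empty((0, 2))
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    keep = np.where(sizes >= 3)[0] + 1
    if keep.size == 0:
        return np.empty((0, 2))
    cy_cx = ndimage.center_of_mass(image - bg.level, labels, index=keep)
    arr = np.asarray(cy_cx, dtype=float)
    return arr[:, ::-1]  # (y, x) -> (x, y)


def estimate_grid(
    image: np.ndarray,
    format_hint: int = 1536,
    anchor: tuple | None = None,
) -> GridSpec:
    """Estimate the colony grid of a plate image.

    ``anchor``, when given, is ``(x, y, angle_degrees)`` and overrides the
    automatically estimated top-left colony center and row angle exactly;
    pitch is still estimated from the image.
    """
    if format_hint not in _FORMATS:
        raise ValueError("format_hint must be 384 or 1536")
    n_rows, n_cols = _FORMATS[format_hint]

    pts = _foreground_centroids(np.asarray(image, dtype=float), _global_background(image))
    if pts.shape[0] < max(10, format_hint // 20):
        raise GridDetectionError(
            f"only {pts.shape[0]} colony-like components found; "
            "no periodic structure detected"
        )

    tree = cKDTree(pts)
    dist, idx = tree.query(pts, k=min(5, pts.shape[0]))
    nn = np.median(dist[:, 1])
    vecs = []
    for i in range(pts.shape[0]):
        for j, d in zip(idx[i, 1:], dist[i, 1:]):
            if 0.5 * nn < d < 1.5 * nn:
                vecs.append(pts[j] - pts[i])
    vecs = np.asarray(vecs)
    horiz = vecs[np.abs(vecs[:, 0]) > np.abs(vecs[:, 1])]
    horiz = horiz * np.where(horiz[:, :1] < 0, -1.0, 1.0)
    vert = vecs[np.abs(vecs[:, 1]) >= np.abs(vecs[:, 0])]
    vert = vert * np.where(vert[:, 1:] < 0, -1.0, 1.0)
    if horiz.shape[0] < 3 or vert.shape[0] < 3:
        raise GridDetectionError("could not separate row/column neighbor vectors")
    hx, hy = np.median(horiz, axis=0)
    angle = math.degrees(math.atan2(hy, hx))
    pitch_x = float(np.hypot(hx, hy))
    pitch_y = float(np.hypot(*np.median(vert, axis=0)))

    if anchor is not None:
        ax, ay, aangle = anchor
        return GridSpec(n_rows, n_cols, (float(ax), float(ay)), float(aangle),
                        pitch_x, pitch_y)

    # fit grid indices in the de-rotated frame, then regress out origin/pitch
    th = math.radians(angle)
    rot = np.array([[math.cos(th), math.sin(th)], [-math.sin(th), math.cos(th)]])
    prime = pts @ rot.T
    jj = np.round((prime[:, 0] - prime[:, 0].min()) / pitch_x)
    ii = np.round((prime[:, 1] - prime[:, 1].min()) / pitch_y)
    bx, ax_ = np.polynomial.polynomial.polyfit(jj, prime[:, 0], 1)
    by, ay_ = np.polynomial.polynomial.polyfit(ii, prime[:, 1], 1)
    pitch_x, pitch_y = float(ax_), float(ay_)
    origin = np.array([bx, by]) @ np.linalg.inv(rot).T
    return GridSpec(n_rows, n_cols, (float(origin[0]), float(origin[1])),
                    float(angle), pitch_x, pitch_y)


def _walk(image: np.ndarray, cx: int, cy: int, bg: BackgroundModel,
          max_walk: int) -> tuple:
    """Distances to the last foreground pixel in -x, +x, -y, +y; capped flag."""
    h, w = image.shape
    thr = bg.threshold
    dists = []
    capped = False
    for dx, dy in ((-1, 0), (1, 0), (0, -1), (0, 1)):
        d = 0
        for step in range(1, max_walk + 1):
            x, y = cx + dx * step, cy + dy * step
            if not (0 <= x < w and 0 <= y < h):
                d = step - 1
                capped = True
                break
            if image[y, x] <= thr:
                d = step - 1
                break
        else:
            d = max_walk
            capped = True
        dists.append(d)
    return tuple(dists), capped


def measure_colony(
    image: np.ndarray,
    est_center: tuple,
    bg: BackgroundModel,
    window: int = 17,
    max_walk: int = 40,
    n_iterations: int = 2,
    subtract_background: bool = False,
    row: int = -1,
    col: int = -1,
) -> ColonyMeasurement:
    """Measure one colony around an estimated center.

    Centering window and walk positions are clamped to the image; a window
    with no pixel above the background cut yields ``missing=True`` with
    zero integrated density. A walk that hits ``max_walk`` or the image
    edge flags the measurement.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    half = window // 2
    ex, ey = int(round(est_center[0])), int(round(est_center[1]))
    x0, x1 = max(0, ex - half), min(w, ex + half + 1)
    y0, y1 = max(0, ey - half), min(h, ey + half + 1)
    win = image[y0:y1, x0:x1]

    def _missing() -> ColonyMeasurement:
        return ColonyMeasurement(row, col, (float(est_center[0]), float(est_center[1])),
                                 0.0, 0.0, 0.0, 0.0, 0.0, missing=True)

    if win.size == 0 or win.max() <= bg.threshold:
        return _missing()

    weights = np.clip(win - bg.level, 0.0, None)
    total = weights.sum()
    if total <= 0:
        return _missing()
    ys, xs = np.mgrid[y0:y1, x0:x1]
    cx = int(round(float((weights * xs).sum() / total)))
    cy = int(round(float((weights * ys).sum() / total)))
    if image[cy, cx] <= bg.threshold:
        return _missing()

    flagged = False
    left = right = up = down = 0
    for _ in range(max(1, n_iterations)):
        (left, right, up, down), capped = _walk(image, cx, cy, bg, max_walk)
        flagged = flagged or capped
        cx = cx + int(round((right - left) / 2.0))
        cy = cy + int(round((down - up) / 2.0))
        cx = min(max(cx, 0), w - 1)
        cy = min(max(cy, 0), h - 1)

    fx = cx + (right - left) / 2.0 - int(round((right - left) / 2.0))
    fy = cy + (down - up) / 2.0 - int(round((down - up) / 2.0))
    semi_x = (left + right) / 2.0
    semi_y = (up + down) / 2.0

    a, b = max(semi_x, 0.5), max(semi_y, 0.5)
    bx0, bx1 = max(0, int(math.floor(fx - a))), min(w, int(math.ceil(fx + a)) + 1)
    by0, by1 = max(0, int(math.floor(fy - b))), min(h, int(math.ceil(fy + b)) + 1)
    yy, xx = np.mgrid[by0:by1, bx0:bx1]
    inside = ((xx - fx) / a) ** 2 + ((yy - fy) / b) ** 2 <= 1.0
    vals = image[by0:by1, bx0:bx1][inside]
    if vals.size == 0:
        return _missing()
    mean_density = float(vals.mean())
    if subtract_background:
        mean_density = max(mean_density - bg.level, 0.0)
    area = math.pi * a * b
    return ColonyMeasurement(
        row=row,
        col=col,
        center=(float(fx), float(fy)),
        semi_axis_x=semi_x,
        semi_axis_y=semi_y,
        area=area,
        mean_density=mean_density,
        integrated_density=mean_density * area,
        missing=False,
        flagged=flagged,
    )


def estimate_background(image: np.ndarray, grid: GridSpec,
                        margin_fraction: float = 0.35, k: float = 3.0,
                        subsample: int = 2) -> BackgroundModel:
    """Background model from pixels in the inter-colony margins.

    A pixel belongs to the margin if its de-rotated grid coordinates are
    farther than ``margin_fraction`` of a pitch from the nearest grid line
    in both axes, within the grid bounding box.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape
    ys, xs = np.mgrid[0:h:subsample, 0:w:subsample]
    th = math.radians(grid.angle)
    tlx, tly = grid.top_left
    dx, dy = xs - tlx, ys - tly
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    du = np.abs((u + grid.pitch_x / 2) % grid.pitch_x - grid.pitch_x / 2)
    dv = np.abs((v + grid.pitch_y / 2) % grid.pitch_y - grid.pitch_y / 2)
    inbox = (
        (u > -grid.pitch_x / 2)
        & (u < (grid.n_cols - 0.5) * grid.pitch_x)
        & (v > -grid.pitch_y / 2)
        & (v < (grid.n_rows - 0.5) * grid.pitch_y)
    )
    margin = inbox & (du > margin_fraction * grid.pitch_x) & (
        dv > margin_fraction * grid.pitch_y
    )
    vals = image[ys[margin], xs[margin]] if margin.any() else image[ys, xs].ravel()
    level = float(np.median(vals))
    spread = 1.4826 * float(np.median(np.abs(vals - level)))
    return BackgroundModel(level=level, spread=spread, k=k)


def quantify_plate(
    image: np.ndarray,
    grid: GridSpec,
    layout: pd.DataFrame | None = None,
    bg: BackgroundModel | None = None,
    **measure_kw,
) -> pd.DataFrame:
    """Measure every grid position of a plate.

    ``layout`` maps (row, col) to strain IDs; positions absent from the
    layout get strain_id NA. Returns one row per grid position with the
    oval geometry and integrated density; deterministic for a fixed image.
    """
    image = np.asarray(image, dtype=float)
    if bg is None:
        bg = estimate_background(image, grid)
    strain_of = {}
    if layout is not None:
        need = {"row", "col", "strain_id"}
        if not need.issubset(layout.columns):
            raise ValueError(f"layout must have columns {sorted(need)}")
        bad = layout[(layout["row"] >= grid.n_rows) | (layout["col"] >= grid.n_cols)
                     | (layout["row"] < 0) | (layout["col"] < 0)]
        if len(bad):
            raise ValueError("layout positions fall outside the grid")
        if layout.duplicated(["row", "col"]).any():
            warnings.warn("duplicate layout positions; last entry wins")
        strain_of = {(int(r), int(c)): s for r, c, s in
                     zip(layout["row"], layout["col"], layout["strain_id"])}

    centers = grid_centers(grid)
    records = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            m = measure_colony(image, tuple(centers[r, c]), bg,
                               row=r, col=c, **measure_kw)
            records.append(
                {
                    "strain_id": strain_of.get((r, c), np.nan),
                    "row": r,
                    "col": c,
                    "center_x": m.center[0],
                    "center_y": m.center[1],
                    "semi_axis_x": m.semi_axis_x,
                    "semi_axis_y": m.semi_axis_y,
                    "area": m.area,
                    "mean_density": m.mean_density,
                    "integrated_density": m.integrated_density,
                    "missing": m.missing,
                    "flagged": m.flagged,
                }
            )
    return pd.DataFrame(records)
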