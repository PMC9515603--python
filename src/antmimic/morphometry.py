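"""Shape and size traits from binary silhouette masks.

A specimen is photographed in dorsal view and reduced to a binary mask
(foreground = body).  Shape is described by (i) a circularity index,
4·pi·area / perimeter^2, equal to 1 for a disk and smaller for elongated,
articulated bodies, and (ii) a 40-point outline profile: the mask is
straightened along its medial body axis and the body half-width is sampled at
40 evenly spaced stations from the anterior to the posterior end, then
standardized to its maximum.  Size is the body-axis arc length (mm) and the
thicknesses of the appendage segments (femur, tibia, tarsus of four
appendages) measured perpendicular to each segment's local axis at annotated
midpoints.

Appendages are excluded from shape measurements through a second,
body-only mask supplied alongside the full mask; automatic appendage
segmentation is not attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra
from skimage.measure import find_contours, label
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)

SEGMENTS = ("femur", "tibia", "tarsus")
N_OUTLINE_POINTS = 40


@dataclass
class Landmark:
    """Midpoint of one appendage segment with its local axis direction."""

    appendage_id: int  # 1..4
    segment: str  # femur | tibia | tarsus
    x: float  # column, px
    y: float  # row, px
    axis_dx: float
    axis_dy: float

    def __post_init__(self) -> None:
        if self.segment not in SEGMENTS:
            raise ValueError(f"segment must be one of {SEGMENTS}")
        norm = float(np.hypot(self.axis_dx, self.axis_dy))
        if norm == 0:
            raise ValueError("landmark axis direction cannot be zero")
        self.axis_dx /= norm
        self.axis_dy /= norm


@dataclass
class SilhouetteMask:
    """Binary pixel grid of one specimen (row-major, origin top-left).

    ``pixels`` is the whole body including appendages; ``body_only_pixels``
    (if present) has appendages removed and is the substrate of all shape
    measurements.  ``scale`` converts pixels to millimetres.
    """

    pixels: np.ndarray
    scale: float  # mm per pixel
    appendage_landmarks: list[Landmark] = field(default_factory=list)
    body_only_pixels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels) > 0
        if self.scale <= 0:
            raise ValueError("scale must be > 0 (mm per pixel)")
        if self.body_only_pixels is not None:
            self.body_only_pixels = np.asarray(self.body_only_pixels) > 0
            if self.body_only_pixels.shape != self.pixels.shape:
                raise ValueError("body_only_pixels must match pixels shape")
        if self.appendage_landmarks and len(self.appendage_landmarks) != 12:
            raise ValueError(
                "expected 12 landmark entries (4 appendages x 3 segments), "
                f"got {len(self.appendage_landmarks)}"
            )

    @property
    def body(self) -> np.ndarray:
        """The mask used for shape: body-only if supplied, else the full mask."""
        return self.body_only_pixels if self.body_only_pixels is not None else self.pixels


@dataclass
class BodyAxis:
    """Ordered medial polyline, anterior to posterior, in (x, y) pixel coords."""

    points: np.ndarray  # (n, 2) as (x, y)
    scale: float  # mm per pixel

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 2:
            raise ValueError("axis needs at least 2 (x, y) points")

    @property
    def arc_length_px(self) -> float:
        return float(np.sum(np.hypot(*np.diff(self.points, axis=0).T)))

    @property
    def arc_length_mm(self) -> float:
        return self.arc_length_px * self.scale


@dataclass
class OutlineProfile:
    """40 half-width values ordered anterior to posterior."""

    distances: np.ndarray  # mm if raw; unitless if standardized
    standardized: bool = False
    max_raw: float = np.nan  # mm, pre-standardization maximum

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if len(self.distances) != N_OUTLINE_POINTS:
            raise ValueError(f"outline profile must have {N_OUTLINE_POINTS} points")
        if np.any(self.distances < 0):
            raise ValueError("outline distances must be >= 0")

    def standardize(self) -> "OutlineProfile":
        if self.standardized:
            return self
        m = float(self.distances.max())
        if m == 0:
            raise ValueError("cannot standardize an all-zero profile")
        return OutlineProfile(self.distances / m, standardized=True, max_raw=m)

    @property
    def raw(self) -> np.ndarray:
        """Raw (mm) distances, undoing standardization if needed."""
        if self.standardized:
            return self.distances * self.max_raw
        return self.distances


@dataclass
class ShapeTraits:
    circularity: float
    outline: OutlineProfile


@dataclass
class SizeTraits:
    body_length: float  # mm
    appendage_thicknesses: np.ndarray  # 12 values, mm
    mean_thickness: float  # mm


# ---------------------------------------------------------------------------
# helpers


def _require_single_component(mask: np.ndarray) -> None:
    n = int(label(mask, connectivity=2).max())
    if n == 0:
        raise ValueError("mask is empty")
    if n > 1:
        raise ValueError(f"mask has {n} connected components; expected exactly 1")


def _bilinear(mask: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Sample a binary mask with bilinear interpolation at (x, y) points."""
    coords = np.vstack([xy[:, 1], xy[:, 0]])  # map_coordinates wants (row, col)
    return ndimage.map_coordinates(mask.astype(float), coords, order=1, mode="constant")


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Longest geodesic path through a skeleton, as (x, y) pixel coordinates.

    Two sweeps of Dijkstra over the 8-connected skeleton graph (edge weights
    1 and sqrt(2)); robust to small cycles.
    """
    rows, cols = np.nonzero(skel)
    n = len(rows)
    if n == 0:
        raise ValueError("empty skeleton")
    if n == 1:
        return np.array([[cols[0], rows[0]]], dtype=float)
    index = -np.ones(skel.shape, dtype=int)
    index[rows, cols] = np.arange(n)
    src, dst, w = [], [], []
    for dr, dc in _NEIGHBOR_OFFSETS:
        r2, c2 = rows + dr, cols + dc
        ok = (r2 >= 0) & (r2 < skel.shape[0]) & (c2 >= 0) & (c2 < skel.shape[1])
        ok[ok] &= skel[r2[ok], c2[ok]]
        src.append(np.arange(n)[ok])
        dst.append(index[r2[ok], c2[ok]])
        w.append(np.full(ok.sum(), np.hypot(dr, dc)))
    g = sparse.csr_matrix(
        (np.concatenate(w), (np.concatenate(src), np.concatenate(dst))), shape=(n, n)
    )
    d0 = dijkstra(g, indices=0)
    d0[~np.isfinite(d0)] = -1
    a = int(np.argmax(d0))
    da, pred = dijkstra(g, indices=a, return_predecessors=True)
    da[~np.isfinite(da)] = -1
    b = int(np.argmax(da))
    path = [b]
    while path[-1] != a:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    path = np.array(path[::-1])
    return np.column_stack([cols[path], rows[path]]).astype(float)


def _smooth_polyline(pts: np.ndarray, frac: float = 0.05) -> np.ndarray:
    """Moving-average smoothing with window ~frac of the point count."""
    w = max(3, int(round(frac * len(pts))))
    if w % 2 == 0:
        w += 1
    if len(pts) < w:
        return pts
    kernel = np.ones(w) / w
    out = pts.copy()
    # pad with edge replication so the ends are not pulled inward
    for j in range(2):
        padded = np.concatenate([np.full(w // 2, pts[0, j]), pts[:, j], np.full(w // 2, pts[-1, j])])
        out[:, j] = np.convolve(padded, kernel, mode="valid")
    return out


def _resample_polyline(pts: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        return pts[:1]
    n_out = max(2, int(round(total / spacing)) + 1)
    si = np.linspace(0, total, n_out)
    return np.column_stack([np.interp(si, s, pts[:, 0]), np.interp(si, s, pts[:, 1])])


def _trim_path_ends(pts: np.ndarray, edt: np.ndarray, max_frac: float = 0.2) -> np.ndarray:
    """Drop end points that run into corner/branch regions of the skeleton.

    On the central medial segment the clearance (distance transform) equals
    the local half-width; on spurious corner branches it drops toward the
    boundary.  Ends are trimmed while the clearance is well below the body's
    typical half-width, capped at ``max_frac`` of the path per end.
    """
    if len(pts) < 10:
        return pts
    e = edt[np.round(pts[:, 1]).astype(int), np.round(pts[:, 0]).astype(int)]
    ref = np.percentile(e, 60)
    cap = int(max_frac * len(pts))
    i0 = 0
    while i0 < cap and e[i0] < 0.8 * ref:
        i0 += 1
    i1 = len(pts)
    while len(pts) - i1 < cap and e[i1 - 1] < 0.8 * ref:
        i1 -= 1
    if i1 - i0 < 5:
        return pts
    return pts[i0:i1]


def _chord_edges(
    profile: np.ndarray, offsets: np.ndarray, c0: int, level: float = 0.5
) -> tuple[float | None, float | None]:
    """Subpixel edges of the foreground chord containing offset 0.

    ``profile`` holds sampled (smoothed) mask values along a normal; edges are
    located by linear interpolation of the ``level`` crossing.  Returns
    (None, None) when the centre sample is outside the foreground.
    """
    if profile[c0] <= level:
        return None, None
    lo = c0
    while lo - 1 >= 0 and profile[lo - 1] > level:
        lo -= 1
    hi = c0
    while hi + 1 < len(profile) and profile[hi + 1] > level:
        hi += 1
    if lo > 0:
        frac = (profile[lo] - level) / (profile[lo] - profile[lo - 1])
        lo_e = offsets[lo] - frac * (offsets[lo] - offsets[lo - 1])
    else:
        lo_e = offsets[0]
    if hi < len(profile) - 1:
        frac = (profile[hi] - level) / (profile[hi] - profile[hi + 1])
        hi_e = offsets[hi] + frac * (offsets[hi + 1] - offsets[hi])
    else:
        hi_e = offsets[-1]
    return float(lo_e), float(hi_e)


def _path_normals(pts: np.ndarray) -> np.ndarray:
    tang = np.gradient(pts, axis=0)
    tnorm = np.hypot(tang[:, 0], tang[:, 1])
    tnorm[tnorm == 0] = 1.0
    tang = tang / tnorm[:, None]
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def _recenter_on_chords(pts: np.ndarray, mask: np.ndarray, max_half: int = 64) -> np.ndarray:
    """Move each point to the midpoint of the foreground chord along its normal."""
    normals = _path_normals(pts)
    offsets = np.arange(-max_half, max_half + 1, dtype=float)
    pos = pts[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    vals = _bilinear(mask, pos.reshape(-1, 2)).reshape(len(pts), len(offsets)) > 0.5
    center = max_half  # index of offset 0
    out = pts.copy()
    for i in range(len(pts)):
        row = vals[i]
        if not row[center]:
            continue
        lo = center
        while lo - 1 >= 0 and row[lo - 1]:
            lo -= 1
        hi = center
        while hi + 1 < len(row) and row[hi + 1]:
            hi += 1
        mid = offsets[lo] + (offsets[hi] - offsets[lo]) / 2.0
        out[i] = pts[i] + mid * normals[i]
    return out


def _extend_to_boundary(pts: np.ndarray, mask: np.ndarray, max_steps: int = 500) -> np.ndarray:
    """Extend both polyline ends along their tangents until leaving the mask.

    Skeletons terminate about half a body-width short of the silhouette tips;
    extension recovers the full anterior/posterior extent of the body axis.
    """
    out = [pts]
    for end in (0, -1):
        k = max(8, min(int(0.15 * len(pts)), len(pts) - 1))
        window = pts[:k] if end == 0 else pts[-k:]
        centered = window - window.mean(axis=0)
        # principal direction of the end window, oriented outward
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        tangent = vt[0]
        outward = pts[end] - window.mean(axis=0)
        if tangent @ outward < 0:
            tangent = -tangent
        if np.hypot(*tangent) == 0:
            continue
        steps = []
        p = pts[end].copy()
        for _ in range(max_steps):
            p = p + tangent * 0.5
            if not (0 <= p[1] < mask.shape[0] and 0 <= p[0] < mask.shape[1]):
                break
            if _bilinear(mask, p[None, :])[0] < 0.5:
                break
            steps.append(p.copy())
        if steps:
            if end == 0:
                out.insert(0, np.array(steps[::-1]))
            else:
                out.append(np.array(steps))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# operations


def straighten_mask(mask: SilhouetteMask) -> tuple[np.ndarray, BodyAxis]:
    """Straighten a body silhouette along its medial axis.

    The body-only mask is skeletonized, the longest geodesic skeleton path is
    taken as the medial axis, extended to the silhouette tips, smoothed and
    resampled at 1-px spacing; cross-sections perpendicular to the axis are
    then mapped into a straight frame whose centre row is the axis.

    Returns the straightened boolean mask and the body axis.
    """
    body = mask.body
    _require_single_component(body)
    rows, cols = np.nonzero(body)
    height = rows.max() - rows.min() + 1
    width = cols.max() - cols.min() + 1
    if min(height, width) >= max(height, width):
        logger.warning("mask is as wide as it is long; straightening may be unstable")

    skel = skeletonize(body)
    path = _longest_skeleton_path(skel)
    if len(path) < 2:
        raise ValueError("degenerate skeleton; cannot extract a body axis")
    # skeletons of blunt shapes fork toward the corners; trim each end of the
    # path by the local half-width so only the central axis remains, then
    # re-extend along the (now central) tangent to the silhouette tips
    edt = ndimage.distance_transform_edt(body)
    path = _trim_path_ends(path, edt)
    path = _extend_to_boundary(path, body)
    path = _resample_polyline(path, spacing=1.0)
    path = _smooth_polyline(path, frac=0.05)
    path = _resample_polyline(path, spacing=1.0)
    # midline refinement: skeleton paths drift off-centre near blunt ends, so
    # re-centre each point on the midpoint of the mask chord along its normal
    for _ in range(2):
        path = _recenter_on_chords(path, body)
        path = _smooth_polyline(path, frac=0.05)
        path = _resample_polyline(path, spacing=1.0)
    # refinement pulls the tips inward; restore the full anterior/posterior extent
    path = _extend_to_boundary(path, body)
    path = _resample_polyline(path, spacing=1.0)
    # orient anterior (leftmost end in image x) first for a stable convention
    if path[0, 0] > path[-1, 0]:
        path = path[::-1]
    axis = BodyAxis(path, mask.scale)

    # tangents and unit normals along the axis
    tang = np.gradient(path, axis=0)
    tnorm = np.hypot(tang[:, 0], tang[:, 1])
    tnorm[tnorm == 0] = 1.0
    tang = tang / tnorm[:, None]
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])

    # cross-sections: subpixel chord edges along each normal, rasterized as
    # round(chord width) rows centred on the chord midpoint — this avoids the
    # half-pixel flicker a plain threshold re-binarization would produce
    half = int(np.ceil(edt.max())) + 3
    step = 0.25
    offsets = np.arange(-half, half + step, step)
    smooth_body = ndimage.gaussian_filter(body.astype(float), 0.6)
    pos = path[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    coords = np.vstack([pos.reshape(-1, 2)[:, 1], pos.reshape(-1, 2)[:, 0]])
    vals = ndimage.map_coordinates(smooth_body, coords, order=1).reshape(len(path), len(offsets))
    c0 = len(offsets) // 2  # index of offset 0
    frame_half = half + 2
    straightened = np.zeros((2 * frame_half + 1, len(path)), dtype=bool)
    for i in range(len(path)):
        lo_e, hi_e = _chord_edges(vals[i], offsets, c0)
        if lo_e is None:
            continue
        n_rows = int(round(hi_e - lo_e))
        if n_rows <= 0:
            continue
        # round the midpoint first so near-zero jitter cannot flip the row
        # placement of an even-width chord between the two centred choices
        j0 = int(round((lo_e + hi_e) / 2.0)) - n_rows // 2
        r0 = frame_half + j0
        straightened[max(r0, 0) : r0 + n_rows, i] = True
    return straightened, axis


def compute_circularity(mask: SilhouetteMask) -> float:
    """Circularity index 4*pi*area / perimeter^2 of the body-only mask.

    The perimeter is measured subpixel: the binary image is smoothed with a
    small Gaussian (sigma 1.5 px) and the 0.5 iso-contour polygon length is
    taken.  Naive pixel-edge counting overestimates the perimeter of smooth
    or oblique boundaries and would bias the index downward; raw
    marching-squares contours share a milder version of the same bias.
    """
    body = mask.body
    if not body.any():
        raise ValueError("mask is empty")
    _require_single_component(body)
    area = float(body.sum())
    padded = np.pad(body, 4).astype(float)
    smooth = ndimage.gaussian_filter(padded, 1.5)
    contours = find_contours(smooth, 0.5)
    perim = float(sum(np.sum(np.hypot(*np.diff(c, axis=0).T)) for c in contours))
    if perim == 0:
        raise ValueError("mask too small to trace a boundary")
    return 4.0 * np.pi * area / perim**2


def compute_outline_profile(
    straightened: np.ndarray, scale: float, n_points: int = N_OUTLINE_POINTS
) -> OutlineProfile:
    """Half-width profile at ``n_points`` stations along the straightened body.

    Stations sit at the centres of ``n_points`` equal slices of the body
    length.  At each station the distance from the axis (centre row) to the
    body edge is measured on both sides and averaged, which makes the profile
    exactly mirror-symmetric.  A station falling in a gap contributes 0.
    """
    straightened = np.asarray(straightened) > 0
    col_any = straightened.any(axis=0)
    if not col_any.any():
        raise ValueError("straightened mask is empty")
    c0, c1 = np.flatnonzero(col_any)[[0, -1]]
    center = straightened.shape[0] // 2
    stations = c0 + (np.arange(n_points) + 0.5) / n_points * (c1 - c0)
    cols = np.clip(np.round(stations).astype(int), c0, c1)
    dists = np.empty(n_points, dtype=float)
    for i, c in enumerate(cols):
        column = straightened[:, c]
        if not column[center]:
            logger.warning("zero-width sample at station %d (gap inside mask)", i)
            dists[i] = 0.0
            continue
        up = 0
        while center - up - 1 >= 0 and column[center - up - 1]:
            up += 1
        down = 0
        while center + down + 1 < len(column) and column[center + down + 1]:
            down += 1
        # distance from axis to the edge just beyond the last foreground pixel
        dists[i] = (up + down) / 2.0 + 0.5
    return OutlineProfile(dists * scale, standardized=False)


def measure_body_length(axis: BodyAxis, scale: float | None = None) -> float:
    """Body length in mm: arc length of the medial axis times the scale."""
    scale = axis.scale if scale is None else scale
    length = axis.arc_length_px * scale
    if length <= 0:
        raise ValueError("axis has zero arc length")
    return length


def measure_appendage_thickness(mask: SilhouetteMask) -> SizeTraits:
    """Thickness of each annotated appendage segment, perpendicular to its axis.

    For every landmark, marches outward from the segment midpoint along the
    perpendicular of its local axis direction until leaving the (full)
    foreground on both sides; thickness is the crossed width in mm.
    """
    if len(mask.appendage_landmarks) != 12:
        raise ValueError("12 appendage landmarks required (4 appendages x 3 segments)")
    full = mask.pixels
    smooth = ndimage.gaussian_filter(full.astype(float), 0.6)
    reach = 16.0  # px; appendages are thin relative to the body
    offsets = np.arange(-reach, reach + 0.1, 0.1)
    values = []
    for lm in mask.appendage_landmarks:
        p0 = np.array([lm.x, lm.y], dtype=float)
        if _bilinear(full, p0[None, :])[0] < 0.5:
            raise ValueError(
                f"landmark appendage {lm.appendage_id} {lm.segment} at "
                f"({lm.x:.1f}, {lm.y:.1f}) is outside the foreground"
            )
        perp = np.array([-lm.axis_dy, lm.axis_dx])
        pos = p0[None, :] + offsets[:, None] * perp[None, :]
        coords = np.vstack([pos[:, 1], pos[:, 0]])
        profile = ndimage.map_coordinates(smooth, coords, order=1)
        lo_e, hi_e = _chord_edges(profile, offsets, len(offsets) // 2)
        if lo_e is None:
            raise ValueError(
                f"landmark appendage {lm.appendage_id} {lm.segment}: no foreground chord"
            )
        values.append((hi_e - lo_e) * mask.scale)
    values = np.array(values)
    # body length is not known here; callers assemble full SizeTraits
    return SizeTraits(
        body_length=np.nan, appendage_thicknesses=values, mean_thickness=float(values.mean())
    )


def species_mean_outline(profiles: list[OutlineProfile]) -> OutlineProfile:
    """Pointwise mean of raw profiles, standardized to its maximum."""
    if len(profiles) == 0:
        raise ValueError("need at least one outline profile")
    raw = np.mean([p.raw for p in profiles], axis=0)
    return OutlineProfile(raw, standardized=False).standardize()


def shape_and_size_traits(mask: SilhouetteMask) -> tuple[ShapeTraits, SizeTraits]:
    """Convenience: full shape + size extraction for one specimen."""
    straightened, axis = straighten_mask(mask)
    outline = compute_outline_profile(straightened, mask.scale)
    shape = ShapeTraits(circularity=compute_circularity(mask), outline=outline)
    length = measure_body_length(axis)
    if mask.appendage_landmarks:
        size = measure_appendage_thickness(mask)
        size.body_length = length
    else:
        size = SizeTraits(length, np.full(12, np.nan), np.nan)
    return shape, size
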