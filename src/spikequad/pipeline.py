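"""Image pipeline: a single spike photograph to a full trait record.

Stages, in run order:

1. ``segment_spike`` — separate background / spike body / awns.  The imaging
   protocol places the spike on a uniform saturated background (blue by
   default), so plant pixels are found by chroma distance to the background
   colour in CIELAB; awns, being much thinner than the spike body, are
   removed by a morphological opening and reported separately.
2. ``straighten`` — extract a smoothed medial axis of the body mask from
   base to apex and measure, at each axis sample, the perpendicular
   half-width to the upper and to the lower contour.  This digitally
   straightens bent spikes: positions are arclengths along the axis.
3. ``fit_quadrangle`` — least-squares fit of the piecewise-linear quadrangle
   height function to each side's half-width profile (grid search over the
   two breakpoints with closed-form height solves, then local refinement).
4. ``contour_descriptors`` — perimeter, areas, circularity, roundness,
   solidity and rugosity of the body silhouette.

``analyze_image`` composes the stages and returns a
:class:`~spikequad.geometry.TraitRecord`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import UnivariateSpline
from scipy.optimize import minimize
from scipy.spatial import ConvexHull
from skimage import color, measure, morphology

from .geometry import (
    AsymmetricQuadrangleFit,
    ContourDescriptors,
    ManualTraits,
    TraitRecord,
    derive_traits,
    symmetrize,
)

__all__ = [
    "DEFAULT_BACKGROUND_RGB",
    "PipelineError",
    "SegmentationError",
    "StraighteningError",
    "FittingError",
    "SpikeImage",
    "SegmentationMasks",
    "WidthProfile",
    "SegmentationConfig",
    "segment_spike",
    "straighten",
    "fit_quadrangle",
    "contour_descriptors",
    "analyze_image",
]

#: Saturated blue of the imaging table backdrop (8-bit RGB).
DEFAULT_BACKGROUND_RGB = (20, 60, 200)


class PipelineError(RuntimeError):
    """Base class for pipeline stage failures; carries the stage name."""

    stage = "pipeline"


class SegmentationError(PipelineError):
    stage = "segmentation"


class StraighteningError(PipelineError):
    stage = "straightening"


class FittingError(PipelineError):
    stage = "fitting"


@dataclass
class SpikeImage:
    """8-bit RGB raster of one spike plus its physical scale (mm per pixel)."""

    rgb: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3 or self.rgb.size == 0:
            raise ValueError("rgb must be a nonempty (H, W, 3) array")
        if not self.scale > 0:
            raise ValueError("scale (mm per pixel) must be positive")


@dataclass
class SegmentationMasks:
    """Disjoint background / spike-body / awn pixel partition of one image."""

    body: np.ndarray
    awn: np.ndarray
    background: np.ndarray

    def __post_init__(self) -> None:
        if self.body.shape != self.awn.shape or self.body.shape != self.background.shape:
            raise ValueError("masks must share one shape")


@dataclass
class WidthProfile:
    """Straightened half-width functions along the rachis axis.

    ``s`` holds strictly increasing axis arclengths in mm from base (0) to
    apex (``length``); ``upper`` and ``lower`` are the perpendicular
    half-widths (mm) to the two contours at each sample.
    """

    s: np.ndarray
    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.lower = np.asarray(self.lower, dtype=float)
        if not (len(self.s) == len(self.upper) == len(self.lower)):
            raise ValueError("s, upper, lower must have equal length")
        if len(self.s) >= 2 and not np.all(np.diff(self.s) > 0):
            raise ValueError("axis arclengths must be strictly increasing")

    @property
    def length(self) -> float:
        return float(self.s[-1]) if len(self.s) else 0.0


@dataclass
class SegmentationConfig:
    """Knobs of the segmentation stage.

    ``chroma_threshold`` is the CIELAB a*b*-plane distance to the background
    colour beyond which a pixel counts as plant; ``opening_radius_px`` is the
    radius of the disk used to strip awns (it must exceed the awn
    half-thickness but stay below the body half-width);
    ``awn_core_radius_px`` sits just above the awn half-thickness and
    controls which shaved boundary detail is returned to the body;
    ``min_object_px`` removes speckle smaller than this area.
    """

    background_rgb: Tuple[int, int, int] = DEFAULT_BACKGROUND_RGB
    chroma_threshold: float = 25.0
    opening_radius_px: int = 5
    awn_core_radius_px: int = 2
    min_object_px: int = 64


def _lab_chroma_distance(rgb: np.ndarray, bg_rgb: Sequence[int]) -> np.ndarray:
    img = rgb.astype(np.float64) / 255.0
    lab = color.rgb2lab(img)
    bg = color.rgb2lab(np.asarray(bg_rgb, dtype=np.float64).reshape(1, 1, 3) / 255.0)
    return np.hypot(lab[..., 1] - bg[0, 0, 1], lab[..., 2] - bg[0, 0, 2])


def segment_spike(
    img: SpikeImage, config: Optional[SegmentationConfig] = None
) -> SegmentationMasks:
    """Partition an image into background, spike body and awn pixels.

    Plant pixels differ in chroma from the uniform backdrop; the body is the
    largest connected component surviving a thickness-based opening, and the
    remaining plant pixels are awns.
    """
    cfg = config or SegmentationConfig()
    dist = _lab_chroma_distance(img.rgb, cfg.background_rgb)
    plant = dist > cfg.chroma_threshold
    plant = morphology.remove_small_objects(plant, max_size=cfg.min_object_px)
    if not plant.any():
        raise SegmentationError("no plant pixels found above chroma threshold")
    opened = morphology.opening(plant, morphology.disk(cfg.opening_radius_px))
    if not opened.any():
        raise SegmentationError(
            "no spike body survives the opening; object thinner than "
            f"{cfg.opening_radius_px} px everywhere"
        )
    labels, n = ndimage.label(opened)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if n > 1 and np.sort(sizes)[-2] > 0.2 * sizes[largest - 1]:
        warnings.warn(
            "multiple large components after opening; keeping the largest",
            stacklevel=2,
        )
    body = labels == largest
    body = _reclaim_boundary_slivers(plant, body, cfg.awn_core_radius_px)
    awn = plant & ~body
    return SegmentationMasks(body=body, awn=awn, background=~plant)


def _reclaim_boundary_slivers(plant: np.ndarray, body: np.ndarray,
                              awn_core_radius_px: int) -> np.ndarray:
    """Return shaved body-boundary pixels to the body, keeping awns out.

    The big opening removes everything locally thinner than its disk: awns,
    but also the tapered spike tips and the crests of spikelet-scale
    boundary bumps.  An awn-free estimate of the plant is built with a much
    smaller opening (just above the awn core thickness) whose boundary loss
    is restored by an equal dilation; the body then grows back into it by
    binary propagation, reclaiming tips and bumps while awns — absent from
    the awn-free mask — stay out.
    """
    disk = morphology.disk(awn_core_radius_px)
    awn_free = morphology.dilation(morphology.opening(plant, disk), disk) & plant
    return ndimage.binary_propagation(body, mask=awn_free | body,
                                      structure=np.ones((3, 3)))


# ---------------------------------------------------------------------------
# Axis extraction / straightening


def _longest_skeleton_path(skel: np.ndarray) -> np.ndarray:
    """Return (n, 2) row/col coordinates of the longest path in a skeleton.

    Double BFS over the 8-connected skeleton graph: the farthest node from an
    arbitrary start, then the farthest node from that one, bound the diameter
    path of the (tree-like) skeleton.
    """
    coords = np.argwhere(skel)
    if len(coords) < 2:
        raise StraighteningError("skeleton too small for axis extraction")
    index = {tuple(c): i for i, c in enumerate(coords)}
    offs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    adj: list[list[int]] = [[] for _ in coords]
    for i, (r, c) in enumerate(coords):
        for dr, dc in offs:
            j = index.get((r + dr, c + dc))
            if j is not None:
                adj[i].append(j)

    def bfs(start: int):
        dist = np.full(len(coords), -1, dtype=int)
        parent = np.full(len(coords), -1, dtype=int)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in adj[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        far = int(np.argmax(dist))
        return far, dist, parent

    a, _, _ = bfs(0)
    b, _, parent = bfs(a)
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return coords[path[::-1]]


def _smooth_axis(path_rc: np.ndarray, smoothing: float) -> Tuple[np.ndarray, np.ndarray]:
    """Fit smoothing splines row(t), col(t) and return dense samples + tangents."""
    t = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(path_rc, axis=0).T))])
    if t[-1] <= 0:
        raise StraighteningError("degenerate axis path")
    # deduplicate parameter values for spline fitting
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, path_rc = t[keep], path_rc[keep]
    k = min(3, len(t) - 1)
    s = smoothing * len(t)
    sp_r = UnivariateSpline(t, path_rc[:, 0], k=k, s=s)
    sp_c = UnivariateSpline(t, path_rc[:, 1], k=k, s=s)
    dense_t = np.linspace(t[0], t[-1], max(64, int(t[-1])))
    pts = np.column_stack([sp_r(dense_t), sp_c(dense_t)])
    tang = np.column_stack([sp_r.derivative()(dense_t), sp_c.derivative()(dense_t)])
    norms = np.linalg.norm(tang, axis=1)
    norms[norms == 0] = 1.0
    return pts, tang / norms[:, None]


def _extend_to_boundary(
    pts: np.ndarray,
    tangents: np.ndarray,
    mask: np.ndarray,
    step: float = 0.5,
    max_px_per_end: Optional[float] = None,
) -> np.ndarray:
    """Prolong the axis tangentially at both ends until it leaves the mask."""
    limit = max_px_per_end if max_px_per_end is not None else 4 * max(mask.shape)
    # end directions from a secant over the outer 15% of the axis: endpoint
    # derivatives wobble where the skeleton meets a wide, rounded apex
    k = max(2, int(0.15 * len(pts)))
    head_dir = pts[0] - pts[k]
    tail_dir = pts[-1] - pts[-k - 1]
    head_dir = head_dir / max(np.linalg.norm(head_dir), 1e-12)
    tail_dir = tail_dir / max(np.linalg.norm(tail_dir), 1e-12)

    def inside(p) -> bool:
        r, c = int(round(p[0])), int(round(p[1]))
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and bool(mask[r, c])

    def march(p0, direction):
        # step along `direction`, snapping up to 2 px perpendicular so a
        # slightly misaligned ray can follow a thin tapering tip
        perp = np.array([-direction[1], direction[0]])
        out = []
        p = p0.copy()
        for _ in range(int(limit / step)):
            q = p + step * direction
            if not inside(q):
                for j in (0.5, -0.5, 1.0, -1.0, 2.0, -2.0):
                    if inside(q + j * perp):
                        q = q + j * perp
                        break
                else:
                    break
            p = q
            out.append(p.copy())
        return np.array(out) if out else np.empty((0, 2))

    head = march(pts[0], head_dir)[::-1]
    tail = march(pts[-1], tail_dir)
    parts = [a for a in (head, pts, tail) if len(a)]
    return np.vstack(parts)


def _halfwidth(point: np.ndarray, normal: np.ndarray, mask: np.ndarray,
               step: float = 0.25) -> float:
    """Distance from an axis point to the mask boundary along one normal."""
    p = point.copy()
    d = 0.0
    limit = float(max(mask.shape))
    while d < limit:
        q = p + (d + step) * normal
        r, c = int(round(q[0])), int(round(q[1]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
            break
        d += step
    return d


def straighten(
    masks: SegmentationMasks,
    scale: float,
    stem_side: str = "left",
    n_samples: int = 200,
    smoothing: float = 4.0,
    min_elongation: float = 1.5,
) -> WidthProfile:
    """Straighten the spike body along its medial axis and sample half-widths.

    The medial axis is the longest skeleton path, smoothed by splines and
    extended tangentially to the base and apex tips.  ``stem_side`` names the
    image border the stem points to ("left"/"right"/"top"/"bottom"); the axis
    end nearer that border becomes the base (arclength 0).  Objects with
    axis-length to width ratio below ``min_elongation`` are flagged as
    degenerate with a warning.
    """
    body = masks.body
    if not body.any():
        raise StraighteningError("empty body mask")
    skel = morphology.skeletonize(body)
    if skel.sum() < 4:
        raise StraighteningError("body mask too small or thin for skeletonization")
    path = _longest_skeleton_path(skel)
    pts, _ = _smooth_axis(path, smoothing)
    # recompute tangents from the smoothed polyline, then extend to the tips:
    # first through the body, then on through the thin tip pixels that the
    # awn/body separation assigned to the awn mask (a tapering tip is as thin
    # as an awn), capped so a stray apex awn cannot dominate the length
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-12)[:, None]
    pts = _extend_to_boundary(pts, tang, body)
    plant = body | masks.awn
    if masks.awn.any():
        arc_so_far = np.hypot(*np.diff(pts, axis=0).T).sum()
        tang = np.gradient(pts, axis=0)
        tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-12)[:, None]
        pts = _extend_to_boundary(pts, tang, plant,
                                  max_px_per_end=0.25 * arc_so_far)

    arc = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(pts, axis=0).T))])
    if arc[-1] <= 0:
        raise StraighteningError("zero-length axis")

    # orient so that arclength 0 is the stem-side end
    ends = {"left": 1, "right": 1, "top": 0, "bottom": 0}
    if stem_side not in ends:
        raise ValueError(f"stem_side must be one of left/right/top/bottom, got {stem_side!r}")
    axis_idx = ends[stem_side]
    first, last = pts[0][axis_idx], pts[-1][axis_idx]
    flip = (first > last) if stem_side in ("left", "top") else (first < last)
    if flip:
        pts = pts[::-1]
        arc = arc[-1] - arc[::-1]

    samples_t = np.linspace(arc[0], arc[-1], n_samples)
    rows = np.interp(samples_t, arc, pts[:, 0])
    cols = np.interp(samples_t, arc, pts[:, 1])
    spts = np.column_stack([rows, cols])
    tang = np.gradient(spts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1), 1e-12)[:, None]
    # left normal of the travel direction = "upper" contour in image terms
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])

    upper = np.array([_halfwidth(p, n, body) for p, n in zip(spts, normals)])
    lower = np.array([_halfwidth(p, -n, body) for p, n in zip(spts, normals)])

    L = arc[-1]
    max_width = float((upper + lower).max())
    if max_width > 0 and L / max_width < min_elongation:
        warnings.warn(
            f"object barely elongated (axis/width = {L / max_width:.2f}); "
            "quadrangle model may be meaningless",
            stacklevel=2,
        )
    return WidthProfile(s=samples_t * scale, upper=upper * scale, lower=lower * scale)


# ---------------------------------------------------------------------------
# Quadrangle fitting


def _side_residual(s, h, L, b1, b2):
    """SSE and optimal heights of the quadrangle ramp for fixed breakpoints."""
    phi1 = np.zeros_like(s)
    phi2 = np.zeros_like(s)
    seg1 = s <= b1
    seg2 = (s > b1) & (s <= b2)
    seg3 = s > b2
    if b1 > 0:
        phi1[seg1] = s[seg1] / b1
    if b2 > b1:
        phi1[seg2] = (b2 - s[seg2]) / (b2 - b1)
        phi2[seg2] = (s[seg2] - b1) / (b2 - b1)
    if L > b2:
        phi2[seg3] = (L - s[seg3]) / (L - b2)
    A = np.column_stack([phi1, phi2])
    g = A.T @ A
    rhs = A.T @ h
    try:
        y = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError:
        y, *_ = np.linalg.lstsq(A, h, rcond=None)
    y = np.clip(y, 0.0, None)
    resid = h - A @ y
    return float(resid @ resid), float(y[0]), float(y[1])


def _fit_side(s: np.ndarray, h: np.ndarray, n_grid: int = 60,
              refine: bool = True) -> Tuple[float, float, float, float, float]:
    """Fit one side's piecewise-linear profile; returns (x1, x2, x3, y1, y2).

    Coarse grid search over the two interior breakpoints (ties broken toward
    the smallest x1 then smallest x2), followed by Nelder-Mead refinement.
    """
    L = float(s[-1])
    # breakpoint candidates at the profile's own sample positions (subsampled
    # to the grid budget): the optimum of the piecewise-linear SSE tends to
    # sit at or near sample positions
    interior = s[1:-1]
    if len(interior) > n_grid:
        idx = np.unique(np.linspace(0, len(interior) - 1, n_grid).astype(int))
        grid = interior[idx]
    else:
        grid = interior
    candidates = []
    for b1 in grid:
        for b2 in grid:
            if b2 <= b1:
                continue
            sse, y1, y2 = _side_residual(s, h, L, b1, b2)
            candidates.append((sse, b1, b2, y1, y2))
    if not candidates:
        raise FittingError("breakpoint grid search failed")
    # ties break toward the smallest b1 then b2 (sort keys in that order)
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    sse, b1, b2, y1, y2 = candidates[0]
    if refine:
        def objective(p):
            bb1, bb2 = p
            if not (0 < bb1 < bb2 < L):
                return sse * 10 + 1e6
            return _side_residual(s, h, L, bb1, bb2)[0]

        # Nelder-Mead from the few best grid starts; the residual surface has
        # local minima between sample positions
        for start in candidates[:3]:
            res = minimize(objective, x0=[start[1], start[2]],
                           method="Nelder-Mead",
                           options={"xatol": L * 1e-4, "fatol": 1e-12,
                                    "maxiter": 400})
            if res.fun < sse - 1e-15:
                b1, b2 = res.x
                sse, y1, y2 = _side_residual(s, h, L, b1, b2)
    return b1, b2 - b1, L - b2, y1, y2


def fit_quadrangle(profile: WidthProfile, n_grid: int = 60,
                   refine: bool = True) -> AsymmetricQuadrangleFit:
    """Fit the two-quadrangle model to a straightened width profile.

    Each side's half-width samples are approximated by the piecewise-linear
    height function rising from (0, 0) to (x1, y1), to (x1+x2, y2), and
    falling to (L, 0), minimizing the sum of squared residuals.  The two
    sides are fitted independently.
    """
    if len(profile.s) < 8:
        raise FittingError("need at least 8 profile samples to fit the model")
    xu1, xu2, xu3, yu1, yu2 = _fit_side(profile.s, profile.upper, n_grid, refine)
    xb1, xb2, xb3, yb1, yb2 = _fit_side(profile.s, profile.lower, n_grid, refine)
    return AsymmetricQuadrangleFit(
        x_u1=xu1, x_u2=xu2, x_u3=xu3, y_u1=yu1, y_u2=yu2,
        x_b1=xb1, x_b2=xb2, x_b3=xb3, y_b1=yb1, y_b2=yb2,
    )


# ---------------------------------------------------------------------------
# Contour descriptors


def _contour_perimeter(mask: np.ndarray) -> Tuple[float, np.ndarray]:
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise SegmentationError("no contour found in mask")
    main = max(contours, key=len)
    # Crofton estimator: unbiased on rasterized smooth boundaries, where the
    # marching-squares polygon overshoots by its staircase
    per = float(measure.perimeter_crofton(mask, directions=4))
    return per, main


def contour_descriptors(masks: SegmentationMasks, scale: float) -> ContourDescriptors:
    """Size and shape indices of the spike body contour.

    Area from the pixel count, perimeter from the marching-squares outer
    contour, convex hull from the contour point set; the major axis is the
    maximum Feret diameter (largest pairwise hull-vertex distance).
    """
    body = masks.body
    if not body.any():
        raise SegmentationError("empty body mask")
    area_px = float(body.sum())
    per_px, contour = _contour_perimeter(body)
    hull = ConvexHull(contour)
    hull_pts = contour[hull.vertices]
    hull_per_px = float(
        np.hypot(*np.diff(np.vstack([hull_pts, hull_pts[:1]]), axis=0).T).sum()
    )
    hull_area_px = float(hull.volume)  # 2-D: volume is the area
    d = hull_pts[:, None, :] - hull_pts[None, :, :]
    feret_px = float(np.sqrt((d ** 2).sum(-1)).max())

    c_SA = area_px * scale ** 2
    c_P = per_px * scale
    c_AA = float(masks.awn.sum()) * scale ** 2
    c_Ci = 4.0 * np.pi * c_SA / c_P ** 2 if c_P > 0 else np.nan
    c_R = 4.0 * c_SA / (np.pi * (feret_px * scale) ** 2) if feret_px > 0 else np.nan
    c_So = area_px / hull_area_px if hull_area_px > 0 else np.nan
    c_Ru = per_px / hull_per_px if hull_per_px > 0 else np.nan
    return ContourDescriptors(c_P=c_P, c_SA=c_SA, c_AA=c_AA,
                              c_Ci=c_Ci, c_R=c_R, c_So=c_So, c_Ru=c_Ru)


# ---------------------------------------------------------------------------
# Composition


def analyze_image(
    img: SpikeImage,
    plant: str = "",
    species: Optional[str] = None,
    accession: Optional[str] = None,
    spike_type: Optional[str] = None,
    manual: Optional[ManualTraits] = None,
    seg_config: Optional[SegmentationConfig] = None,
    stem_side: str = "left",
    n_samples: int = 200,
    n_grid: int = 60,
) -> TraitRecord:
    """Run the full pipeline on one image and assemble a TraitRecord."""
    try:
        masks = segment_spike(img, seg_config)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise SegmentationError(f"segmentation failed: {exc}") from exc
    profile = straighten(masks, img.scale, stem_side=stem_side, n_samples=n_samples)
    fit = fit_quadrangle(profile, n_grid=n_grid)
    model = symmetrize(fit)
    derived = derive_traits(model)
    contour = contour_descriptors(masks, img.scale)
    return TraitRecord(
        plant=plant, species=species, accession=accession, spike_type=spike_type,
        manual=manual, model=model, derived=derived, contour=contour,
    )
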