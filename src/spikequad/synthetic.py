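"""Synthetic spike imagery and trait populations with known ground truth.

The renderer draws the mirrored quadrangle silhouette of a
:class:`~spikequad.geometry.SymmetricQuadrangleModel`, optionally modulated
by a sinusoidal boundary undulation (emulating the spikelet-scale bumps of a
real spike), bent along a circular arc of given curvature, and decorated
with thin awn strokes, composited on a saturated uniform background.  It
returns the image together with the exact body/awn masks and the generative
axis arclength, so every downstream stage can be tested against ground
truth.

The population sampler draws per-plant model parameters, awn areas and
manual traits from truncated-at-zero normal distributions around per-class
means.  Its default parameterization is the published per-species trait
means and standard errors for the eight classes (seven hexaploid wheat
species plus one amphidiploid); standard deviations are reconstructed as
SE * sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull
from skimage import draw, morphology

from .geometry import (
    ContourDescriptors,
    ManualTraits,
    SymmetricQuadrangleModel,
    TraitRecord,
    derive_traits,
    model_polyline,
    spike_density_index,
)
from .pipeline import DEFAULT_BACKGROUND_RGB, SegmentationMasks, SpikeImage

__all__ = [
    "CanvasSizeError",
    "SpikeRenderSpec",
    "ClassSpec",
    "PopulationSpec",
    "render_spike",
    "sample_render_specs",
    "generate_population",
    "SPECIES_TABLE",
    "default_population_spec",
]


class CanvasSizeError(ValueError):
    """The requested model does not fit on an allowed canvas."""


#: Body colour of the rendered spike (wheat straw, 8-bit RGB).
BODY_RGB = (205, 180, 120)


@dataclass
class SpikeRenderSpec:
    """Everything needed to draw one synthetic spike deterministically."""

    model: SymmetricQuadrangleModel
    bump_amplitude_mm: float = 0.0
    bump_count: int = 0
    curvature_per_mm: float = 0.0
    awn_count: int = 0
    awn_length_mm: float = 0.0
    awn_thickness_px: int = 2
    scale: float = 0.2
    background_rgb: Tuple[int, int, int] = DEFAULT_BACKGROUND_RGB
    seed: int = 0
    margin_px: int = 24
    max_canvas_px: int = 4000

    def __post_init__(self) -> None:
        for name in ("bump_amplitude_mm", "awn_length_mm", "curvature_per_mm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def _height_profile(model: SymmetricQuadrangleModel, t: np.ndarray) -> np.ndarray:
    """Quadrangle half-width (mm) at arclengths t along the rachis."""
    x1, x12, L = model.q_x1s, model.q_x1s + model.q_x2s, model.q_L
    return np.interp(t, [0.0, x1, x12, L], [0.0, model.q_y1s, model.q_y2s, 0.0])


def _centerline(t: np.ndarray, curvature: float) -> Tuple[np.ndarray, np.ndarray]:
    """Arclength-parametrized centerline points and unit normals (mm, x-y)."""
    if curvature <= 0:
        pts = np.column_stack([t, np.zeros_like(t)])
        normals = np.tile([0.0, 1.0], (len(t), 1))
        return pts, normals
    R = 1.0 / curvature
    theta = t / R  # arc bends upward, preserving arclength
    pts = np.column_stack([R * np.sin(theta), R * (1.0 - np.cos(theta))])
    normals = np.column_stack([-np.sin(theta), np.cos(theta)])
    return pts, normals


def render_spike(
    spec: SpikeRenderSpec,
) -> Tuple[SpikeImage, SegmentationMasks, float]:
    """Render one spike; returns (image, ground-truth masks, axis arclength mm).

    The silhouette is built by offsetting the (possibly bent) centerline by
    the quadrangle half-width plus the boundary bump term
    ``amp * (1 - cos(2*pi*n*t/L)) / 2`` on each side.  Awns are straight
    strokes rooted on the upper contour, angled toward the apex.
    """
    model = spec.model
    L = model.q_L
    rng = np.random.default_rng(spec.seed)

    n_dense = max(256, int(4 * L / spec.scale / 4))
    t = np.linspace(0.0, L, n_dense)
    h = _height_profile(model, t)
    if spec.bump_amplitude_mm > 0 and spec.bump_count > 0:
        h = h + spec.bump_amplitude_mm * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * spec.bump_count * t / L)
        )
    if spec.curvature_per_mm * L >= math.pi:
        raise ValueError("curvature too strong: arc exceeds a half turn")
    ctr, nrm = _centerline(t, spec.curvature_per_mm)
    upper = ctr + h[:, None] * nrm
    lower = ctr - h[:, None] * nrm
    poly_mm = np.vstack([upper, lower[::-1]])

    # canvas accommodating silhouette + awns + margin
    awn_pad = spec.awn_length_mm if spec.awn_count > 0 else 0.0
    xy_min = poly_mm.min(axis=0) - awn_pad
    xy_max = poly_mm.max(axis=0) + awn_pad
    size_px = (xy_max - xy_min) / spec.scale + 2 * spec.margin_px
    W, H = int(np.ceil(size_px[0])), int(np.ceil(size_px[1]))
    if W > spec.max_canvas_px or H > spec.max_canvas_px:
        raise CanvasSizeError(
            f"canvas {W}x{H} px exceeds the {spec.max_canvas_px} px limit; "
            "increase scale or shrink the model"
        )

    def to_px(p_mm: np.ndarray) -> np.ndarray:
        # image rows grow downward; flip y so 'up' in model space is up
        cols = (p_mm[:, 0] - xy_min[0]) / spec.scale + spec.margin_px
        rows = (xy_max[1] - p_mm[:, 1]) / spec.scale + spec.margin_px
        return np.column_stack([rows, cols])

    body = np.zeros((H, W), dtype=bool)
    rc = to_px(poly_mm)
    rr, cc = draw.polygon(rc[:, 0], rc[:, 1], shape=body.shape)
    body[rr, cc] = True

    awn = np.zeros_like(body)
    if spec.awn_count > 0 and spec.awn_length_mm > 0:
        # root awns on the upper contour of the central/apical region,
        # angled toward the apex like real awns
        roots = np.linspace(0.35, 0.95, spec.awn_count) * (n_dense - 1)
        for k, ridx in enumerate(roots.astype(int)):
            p0 = upper[ridx]
            direction = nrm[ridx] + 1.4 * np.array(
                [math.cos(0.25 * (rng.random() - 0.5)), 0.0]
            )
            direction = direction / np.linalg.norm(direction)
            p1 = p0 + spec.awn_length_mm * direction
            a0, a1 = to_px(np.array([p0]))[0], to_px(np.array([p1]))[0]
            rr, cc = draw.line(int(a0[0]), int(a0[1]), int(a1[0]), int(a1[1]))
            keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
            stroke = np.zeros_like(body)
            stroke[rr[keep], cc[keep]] = True
            if spec.awn_thickness_px > 1:
                stroke = morphology.dilation(
                    stroke, morphology.disk(spec.awn_thickness_px // 2)
                )
            awn |= stroke
    awn &= ~body

    rgb = np.empty((H, W, 3), dtype=np.uint8)
    rgb[:] = spec.background_rgb
    rgb[body] = BODY_RGB
    rgb[awn] = BODY_RGB
    img = SpikeImage(rgb=rgb, scale=spec.scale)
    masks = SegmentationMasks(body=body, awn=awn, background=~(body | awn))
    return img, masks, L


# ---------------------------------------------------------------------------
# Population sampling

#: Published per-species summaries (n; trait mean, standard error) used as the
#: default class parameterization.  Keys: species code -> trait -> (mean, SE).
SPECIES_TABLE: Dict[str, dict] = {
    "ASP": {"n": 9, "SL": (90.44, 6.06), "SFW": (8.22, 0.40), "SSW": (6.33, 0.33),
            "SSC": (19.22, 1.19),
            "q_x1s": (31.70, 5.46), "q_x2s": (59.96, 8.20), "q_x3s": (9.75, 3.85),
            "q_y1s": (3.36, 0.31), "q_y2s": (2.81, 0.80), "c_AA": (5.38, 1.18),
            "type": "spelt"},
    "TAE": {"n": 50, "SL": (74.64, 2.25), "SFW": (9.12, 0.25), "SSW": (7.52, 0.24),
            "SSC": (15.60, 0.41),
            "q_x1s": (30.72, 2.07), "q_x2s": (45.00, 2.99), "q_x3s": (10.98, 1.51),
            "q_y1s": (3.71, 0.23), "q_y2s": (3.98, 0.22), "c_AA": (21.82, 1.81),
            "type": "normal"},
    "TAN": {"n": 10, "SL": (39.70, 1.35), "SFW": (8.70, 0.15), "SSW": (6.90, 0.18),
            "SSC": (17.60, 0.37),
            "q_x1s": (23.70, 5.08), "q_x2s": (19.55, 2.57), "q_x3s": (6.36, 2.46),
            "q_y1s": (3.60, 0.51), "q_y2s": (3.51, 0.46), "c_AA": (7.18, 0.76),
            "type": "compact"},
    "TCO": {"n": 63, "SL": (51.56, 0.89), "SFW": (11.65, 0.24), "SSW": (8.29, 0.20),
            "SSC": (16.51, 0.41),
            "q_x1s": (29.60, 2.21), "q_x2s": (33.07, 1.52), "q_x3s": (6.78, 0.61),
            "q_y1s": (4.69, 0.26), "q_y2s": (6.53, 0.25), "c_AA": (96.73, 0.02),
            "type": "compact"},
    "TMA": {"n": 9, "SL": (84.22, 3.46), "SFW": (6.33, 0.33), "SSW": (6.22, 0.36),
            "SSC": (18.78, 0.66),
            "q_x1s": (22.29, 4.70), "q_x2s": (55.31, 4.03), "q_x3s": (10.28, 2.48),
            "q_y1s": (3.32, 0.29), "q_y2s": (2.10, 0.18), "c_AA": (46.64, 10.77),
            "type": "spelt"},
    "TSP": {"n": 14, "SL": (94.71, 5.02), "SFW": (6.46, 0.19), "SSW": (5.96, 0.13),
            "SSC": (15.36, 0.39),
            "q_x1s": (27.42, 4.33), "q_x2s": (65.68, 4.11), "q_x3s": (14.48, 3.36),
            "q_y1s": (2.80, 0.55), "q_y2s": (2.72, 0.63), "c_AA": (57.14, 15.20),
            "type": "spelt"},
    "TSH": {"n": 18, "SL": (35.83, 1.17), "SFW": (8.22, 0.32), "SSW": (6.61, 0.24),
            "SSC": (14.89, 0.27),
            "q_x1s": (24.31, 3.02), "q_x2s": (13.60, 2.05), "q_x3s": (8.46, 1.84),
            "q_y1s": (3.42, 0.61), "q_y2s": (4.41, 0.60), "c_AA": (11.12, 1.09),
            "type": "compact"},
    "TYU": {"n": 8, "SL": (87.00, 3.76), "SFW": (7.38, 0.46), "SSW": (7.00, 0.46),
            "SSC": (17.13, 1.06),
            "q_x1s": (16.27, 4.76), "q_x2s": (61.96, 9.47), "q_x3s": (6.17, 2.59),
            "q_y1s": (3.06, 0.51), "q_y2s": (3.17, 0.59), "c_AA": (78.24, 17.77),
            "type": "normal"},
}

_MODEL_PARAMS = ("q_x1s", "q_x2s", "q_x3s", "q_y1s", "q_y2s")
_MANUAL_PARAMS = ("SL", "SFW", "SSW", "SSC")


@dataclass
class ClassSpec:
    """Per-class sampling distribution: means and SDs per parameter (mm)."""

    label: str
    model_mean: Dict[str, float]
    model_sd: Dict[str, float]
    manual_mean: Dict[str, float] = field(default_factory=dict)
    manual_sd: Dict[str, float] = field(default_factory=dict)
    awn_area_mean: float = 0.0
    awn_area_sd: float = 0.0
    spike_type: Optional[str] = None
    # rendering-only knobs
    bump_amplitude_mm: float = 0.5
    bump_count: int = 16
    curvature_per_mm: float = 0.0
    awn_count: int = 0
    awn_length_mm: float = 0.0

    def __post_init__(self) -> None:
        for d in (self.model_sd, self.manual_sd):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"standard deviation for {k} must be >= 0")


@dataclass
class PopulationSpec:
    classes: List[ClassSpec]
    n_per_class: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class <= 0:
            raise ValueError("n_per_class must be positive")
        if not self.classes:
            raise ValueError("need at least one class")


def default_population_spec(n_per_class: int = 25, seed: int = 0) -> PopulationSpec:
    """Population spec for the eight study classes at the published scale."""
    classes = []
    for code, row in SPECIES_TABLE.items():
        n = row["n"]
        sd = {k: row[k][1] * math.sqrt(n) for k in _MODEL_PARAMS}
        mean = {k: row[k][0] for k in _MODEL_PARAMS}
        msd = {k: row[k][1] * math.sqrt(n) for k in _MANUAL_PARAMS}
        mmean = {k: row[k][0] for k in _MANUAL_PARAMS}
        classes.append(ClassSpec(
            label=code,
            model_mean=mean, model_sd=sd,
            manual_mean=mmean, manual_sd=msd,
            awn_area_mean=row["c_AA"][0],
            awn_area_sd=row["c_AA"][1] * math.sqrt(n),
            spike_type=row["type"],
        ))
    return PopulationSpec(classes=classes, n_per_class=n_per_class, seed=seed)


def sample_render_specs(
    n: int,
    seed: int = 0,
    bumps_and_bends: bool = False,
    scale: float = 0.25,
) -> List[SpikeRenderSpec]:
    """Sample render specs cycling through the eight study classes.

    Model parameters are drawn from the per-class truncated normals with a
    realism floor: 10% of the class mean for segment lengths and 1.5 mm for
    the half-widths (the thinnest species in hexaploid wheat averages about
    2 mm; a sub-millimetre spike cannot be photographed, let alone fitted).
    With
    ``bumps_and_bends`` the renders add spikelet-scale boundary undulation
    (0.5 mm amplitude, one bump per ~6 mm), a gentle bend (curvature
    0.003 / mm) and five 25 mm awns — the regime of real table-protocol
    imagery; otherwise silhouettes are clean, straight and awnless.
    """
    rng = np.random.default_rng(seed)
    classes = default_population_spec().classes
    specs: List[SpikeRenderSpec] = []
    for i in range(n):
        cls = classes[i % len(classes)]
        params = {}
        for k in _MODEL_PARAMS:
            mean = cls.model_mean[k]
            low = max(0.1 * mean, 1.5) if k.startswith("q_y") else 0.1 * mean
            params[k] = _truncated_normal(rng, mean, cls.model_sd[k], low=low)
        model = SymmetricQuadrangleModel(**params)
        if bumps_and_bends:
            spec = SpikeRenderSpec(
                model=model, scale=scale,
                bump_amplitude_mm=0.5,
                bump_count=max(4, int(model.q_L / 6.0)),
                curvature_per_mm=0.003,
                awn_count=5, awn_length_mm=25.0,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            spec = SpikeRenderSpec(model=model, scale=scale,
                                   seed=int(rng.integers(0, 2**31 - 1)))
        specs.append(spec)
    return specs


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float = 0.0, max_tries: int = 200) -> float:
    """Normal draw resampled until >= low (degenerate SD returns the mean)."""
    if sd == 0:
        return max(mean, low)
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if v >= low:
            return v
    return max(mean, low)


def _analytic_contour(model: SymmetricQuadrangleModel, awn_area: float,
                      rugosity: float = 1.12) -> ContourDescriptors:
    """Contour descriptors computed from the model polygon itself.

    The body silhouette is taken to be the mirrored quadrangle: c_SA = 2 q_S,
    perimeter from the polygon edges scaled by a fixed rugosity factor
    (boundary undulation makes real contours longer than their hull),
    Feret diameter from the vertex set.
    """
    poly = model_polyline(model)[:-1]
    edges = np.diff(np.vstack([poly, poly[:1]]), axis=0)
    per = float(np.hypot(edges[:, 0], edges[:, 1]).sum())
    derived = derive_traits(model)
    area = 2.0 * derived.q_S
    if area <= 0:
        return ContourDescriptors(per, 0.0, awn_area, np.nan, np.nan, np.nan, np.nan)
    hull = ConvexHull(poly)
    hull_pts = poly[hull.vertices]
    hull_per = float(np.hypot(*np.diff(np.vstack([hull_pts, hull_pts[:1]]),
                                       axis=0).T).sum())
    hull_area = float(hull.volume)
    d = hull_pts[:, None, :] - hull_pts[None, :, :]
    feret = float(np.sqrt((d ** 2).sum(-1)).max())
    c_P = per * rugosity
    return ContourDescriptors(
        c_P=c_P,
        c_SA=area,
        c_AA=awn_area,
        c_Ci=4.0 * np.pi * area / c_P ** 2,
        c_R=4.0 * area / (np.pi * feret ** 2),
        c_So=area / hull_area,
        c_Ru=c_P / hull_per,
    )


def _sample_record(rng: np.random.Generator, cls: ClassSpec, plant: str) -> TraitRecord:
    params = {k: _truncated_normal(rng, cls.model_mean.get(k, 0.0),
                                   cls.model_sd.get(k, 0.0))
              for k in _MODEL_PARAMS}
    # guard against a fully collapsed base
    if params["q_x1s"] + params["q_x2s"] + params["q_x3s"] <= 0:
        params["q_x2s"] = max(cls.model_mean.get("q_x2s", 1.0), 1.0)
    model = SymmetricQuadrangleModel(**params)
    manual = None
    if cls.manual_mean:
        sl = _truncated_normal(rng, cls.manual_mean.get("SL", 1.0),
                               cls.manual_sd.get("SL", 0.0), low=1e-6)
        ssc = max(1.0, round(_truncated_normal(
            rng, cls.manual_mean.get("SSC", 1.0), cls.manual_sd.get("SSC", 0.0),
            low=1.0)))
        manual = ManualTraits(
            SL=sl,
            SFW=_truncated_normal(rng, cls.manual_mean.get("SFW", 0.0),
                                  cls.manual_sd.get("SFW", 0.0)),
            SSW=_truncated_normal(rng, cls.manual_mean.get("SSW", 0.0),
                                  cls.manual_sd.get("SSW", 0.0)),
            SSC=ssc,
            SDI=spike_density_index(ssc, sl),
        )
    awn_area = _truncated_normal(rng, cls.awn_area_mean, cls.awn_area_sd)
    return TraitRecord(
        plant=plant,
        species=cls.label,
        accession=None,
        spike_type=cls.spike_type,
        manual=manual,
        model=model,
        derived=derive_traits(model),
        contour=_analytic_contour(model, awn_area),
    )


def generate_population(
    spec: PopulationSpec, mode: str = "traits"
) -> pd.DataFrame | List[Tuple[SpikeRenderSpec, TraitRecord]]:
    """Sample a labelled population from per-class truncated normals.

    ``mode="traits"`` derives the full trait table analytically from the
    sampled models (fast path for statistics and classification tests) and
    returns a DataFrame.  ``mode="render"`` returns a list of
    (SpikeRenderSpec, TraitRecord) pairs ready for :func:`render_spike`.
    """
    if mode not in ("traits", "render"):
        raise ValueError(f"mode must be 'traits' or 'render', got {mode!r}")
    rng = np.random.default_rng(spec.seed)
    rows: List[TraitRecord] = []
    renders: List[Tuple[SpikeRenderSpec, TraitRecord]] = []
    for cls in spec.classes:
        for i in range(spec.n_per_class):
            plant = f"{cls.label}_{i:03d}"
            rec = _sample_record(rng, cls, plant)
            rows.append(rec)
            if mode == "render":
                renders.append((
                    SpikeRenderSpec(
                        model=rec.model,
                        bump_amplitude_mm=cls.bump_amplitude_mm,
                        bump_count=cls.bump_count,
                        curvature_per_mm=cls.curvature_per_mm,
                        awn_count=cls.awn_count,
                        awn_length_mm=cls.awn_length_mm,
                        seed=int(rng.integers(0, 2**31 - 1)),
                    ),
                    rec,
                ))
    if mode == "render":
        return renders
    return pd.DataFrame([r.to_dict() for r in rows])
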