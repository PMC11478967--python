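"""Quadrangle spike-shape model and derived morphometric traits.

A wheat spike silhouette, laid flat with the rachis horizontal, is
approximated by two quadrangles sharing the rachis as a common base: one for
the upper contour, one for the lower.  Each quadrangle is described by three
base segment lengths (basal, central, apical) and two heights (basal and
apical widths).  Averaging the upper and lower parameters yields a single
mirror-symmetric model with five independent parameters, from which a full
set of derived traits (segment areas, width index, length- and
area-normalized shares) follows analytically.

All lengths are millimetres, areas square millimetres.  The spike density
index SDI = (SSC - 1) * 100 / SL (SL in mm) is spikelets per decimetre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

__all__ = [
    "SPECIES_CODES",
    "SPIKE_TYPES",
    "MANUAL_TRAIT_NAMES",
    "MODEL_TRAIT_NAMES",
    "DERIVED_TRAIT_NAMES",
    "CONTOUR_TRAIT_NAMES",
    "DIGITAL_TRAIT_NAMES",
    "ALL_TRAIT_NAMES",
    "InvalidModelError",
    "DegenerateModelError",
    "AsymmetricQuadrangleFit",
    "SymmetricQuadrangleModel",
    "DerivedQuadrangleTraits",
    "ContourDescriptors",
    "ManualTraits",
    "TraitRecord",
    "symmetrize",
    "derive_traits",
    "spike_density_index",
    "model_polyline",
    "polygon_area",
]

#: Species / amphidiploid codes used as classification labels.
SPECIES_CODES = ("ASP", "TAE", "TAN", "TCO", "TMA", "TSP", "TSH", "TYU")

#: Dorofeev spike-shape types.
SPIKE_TYPES = ("compact", "normal", "spelt")

MANUAL_TRAIT_NAMES = ("SL", "SFW", "SSW", "SSC", "SDI")
MODEL_TRAIT_NAMES = ("q_x1s", "q_x2s", "q_x3s", "q_y1s", "q_y2s")
DERIVED_TRAIT_NAMES = (
    "q_L", "q_S1", "q_S2", "q_S3", "q_S", "q_ym",
    "q_x1ns", "q_x2ns", "q_x3ns", "q_y1ns", "q_y2ns",
    "q_S1S", "q_S2S", "q_S3S",
)
CONTOUR_TRAIT_NAMES = ("c_P", "c_SA", "c_AA", "c_Ci", "c_R", "c_So", "c_Ru")
#: The 26 image-derived traits, in canonical column order.
DIGITAL_TRAIT_NAMES = MODEL_TRAIT_NAMES + DERIVED_TRAIT_NAMES + CONTOUR_TRAIT_NAMES
#: All 31 traits (5 manual + 26 digital).
ALL_TRAIT_NAMES = MANUAL_TRAIT_NAMES + DIGITAL_TRAIT_NAMES


class InvalidModelError(ValueError):
    """A quadrangle model violates its invariants (e.g. negative length)."""


class DegenerateModelError(ValueError):
    """A model is degenerate for the requested derivation (e.g. zero length)."""


def _check_nonnegative(obj, names) -> None:
    for name in names:
        v = getattr(obj, name)
        if not math.isfinite(v) or v < 0:
            raise InvalidModelError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class AsymmetricQuadrangleFit:
    """Independently fitted upper (u) and lower (b) quadrangle parameters, mm."""

    x_u1: float
    x_u2: float
    x_u3: float
    y_u1: float
    y_u2: float
    x_b1: float
    x_b2: float
    x_b3: float
    y_b1: float
    y_b2: float

    def __post_init__(self) -> None:
        _check_nonnegative(self, [f.name for f in fields(self)])
        if self.x_u1 + self.x_u2 + self.x_u3 <= 0:
            raise InvalidModelError("upper base length must be positive")
        if self.x_b1 + self.x_b2 + self.x_b3 <= 0:
            raise InvalidModelError("lower base length must be positive")


@dataclass(frozen=True)
class SymmetricQuadrangleModel:
    """The five independent parameters of the mirror-symmetric model, mm.

    ``q_x1s``, ``q_x2s``, ``q_x3s`` are the basal, central and apical segment
    lengths along the rachis; ``q_y1s`` and ``q_y2s`` are the half-widths at
    the two interior breakpoints (basal and apical segment widths).
    """

    q_x1s: float
    q_x2s: float
    q_x3s: float
    q_y1s: float
    q_y2s: float

    def __post_init__(self) -> None:
        _check_nonnegative(self, [f.name for f in fields(self)])
        if self.q_x1s + self.q_x2s + self.q_x3s <= 0:
            raise InvalidModelError("total base length must be positive")

    @property
    def q_L(self) -> float:
        return self.q_x1s + self.q_x2s + self.q_x3s

    def scaled(self, k: float) -> "SymmetricQuadrangleModel":
        return SymmetricQuadrangleModel(
            self.q_x1s * k, self.q_x2s * k, self.q_x3s * k,
            self.q_y1s * k, self.q_y2s * k,
        )


@dataclass(frozen=True)
class DerivedQuadrangleTraits:
    q_L: float
    q_S1: float
    q_S2: float
    q_S3: float
    q_S: float
    q_ym: float
    q_x1ns: float
    q_x2ns: float
    q_x3ns: float
    q_y1ns: float
    q_y2ns: float
    q_S1S: float
    q_S2S: float
    q_S3S: float


@dataclass(frozen=True)
class ContourDescriptors:
    """Whole-contour size and shape indices of the spike body silhouette.

    ``c_Ci`` (circularity) = 4*pi*A/P**2, ``c_R`` (roundness) =
    4*A/(pi*F**2) with F the maximum Feret diameter, ``c_So`` (solidity) =
    A / convex-hull area, ``c_Ru`` (rugosity) = P / convex-hull perimeter.
    All four equal 1 for a disk.
    """

    c_P: float
    c_SA: float
    c_AA: float
    c_Ci: float
    c_R: float
    c_So: float
    c_Ru: float


@dataclass(frozen=True)
class ManualTraits:
    """Hand-measured traits: lengths in mm, SSC a count, SDI per decimetre."""

    SL: float
    SFW: float
    SSW: float
    SSC: float
    SDI: Optional[float] = None

    def __post_init__(self) -> None:
        if self.SL <= 0:
            raise InvalidModelError(f"SL must be positive, got {self.SL!r}")
        if self.SSC < 1:
            raise InvalidModelError(f"SSC must be >= 1, got {self.SSC!r}")
        if self.SDI is None:
            object.__setattr__(self, "SDI", spike_density_index(self.SSC, self.SL))


@dataclass
class TraitRecord:
    """All traits of one plant's spike, plus its identity labels."""

    plant: str
    species: Optional[str] = None
    accession: Optional[str] = None
    spike_type: Optional[str] = None
    manual: Optional[ManualTraits] = None
    model: Optional[SymmetricQuadrangleModel] = None
    derived: Optional[DerivedQuadrangleTraits] = None
    contour: Optional[ContourDescriptors] = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """Flatten to one row keyed by the canonical trait abbreviations."""
        row: dict = {
            "plant": self.plant,
            "species": self.species,
            "accession": self.accession,
            "spike_type": self.spike_type,
        }
        for name in ALL_TRAIT_NAMES:
            row[name] = np.nan
        if self.manual is not None:
            for name in MANUAL_TRAIT_NAMES:
                row[name] = getattr(self.manual, name)
        if self.model is not None:
            for name in MODEL_TRAIT_NAMES:
                row[name] = getattr(self.model, name)
        if self.derived is not None:
            for name in DERIVED_TRAIT_NAMES:
                row[name] = getattr(self.derived, name)
        if self.contour is not None:
            for name in CONTOUR_TRAIT_NAMES:
                row[name] = getattr(self.contour, name)
        row.update(self.extras)
        return row

    @classmethod
    def from_dict(cls, row: dict) -> "TraitRecord":
        def _get(name):
            v = row.get(name, np.nan)
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        rec = cls(
            plant=str(row.get("plant", "")),
            species=row.get("species") or None,
            accession=row.get("accession") or None,
            spike_type=row.get("spike_type") or None,
        )
        if np.isfinite(_get("SL")) and np.isfinite(_get("SSC")):
            sdi = _get("SDI")
            rec.manual = ManualTraits(
                SL=_get("SL"), SFW=_get("SFW"), SSW=_get("SSW"),
                SSC=_get("SSC"), SDI=sdi if np.isfinite(sdi) else None,
            )
        model_vals = [_get(n) for n in MODEL_TRAIT_NAMES]
        if all(np.isfinite(v) for v in model_vals):
            rec.model = SymmetricQuadrangleModel(*model_vals)
            rec.derived = derive_traits(rec.model)
        contour_vals = [_get(n) for n in CONTOUR_TRAIT_NAMES]
        if all(np.isfinite(v) for v in contour_vals):
            rec.contour = ContourDescriptors(*contour_vals)
        return rec


def symmetrize(fit: AsymmetricQuadrangleFit) -> SymmetricQuadrangleModel:
    """Average the upper and lower quadrangle parameters into one model.

    Each symmetric parameter is the arithmetic mean of the corresponding
    upper and lower parameter, e.g. ``q_x1s = (x_u1 + x_b1) / 2``.
    """
    return SymmetricQuadrangleModel(
        q_x1s=(fit.x_u1 + fit.x_b1) / 2.0,
        q_x2s=(fit.x_u2 + fit.x_b2) / 2.0,
        q_x3s=(fit.x_u3 + fit.x_b3) / 2.0,
        q_y1s=(fit.y_u1 + fit.y_b1) / 2.0,
        q_y2s=(fit.y_u2 + fit.y_b2) / 2.0,
    )


def derive_traits(model: SymmetricQuadrangleModel) -> DerivedQuadrangleTraits:
    """Compute all derived quadrangle traits from the five model parameters.

    The half-spike quadrangle has vertices (0,0), (q_x1s,q_y1s),
    (q_x1s+q_x2s,q_y2s), (q_L,0); splitting it vertically at the two interior
    breakpoints gives a basal triangle, central trapezoid and apical triangle:

        q_S1 = q_x1s*q_y1s/2
        q_S2 = q_x2s*(q_y1s+q_y2s)/2
        q_S3 = q_x3s*q_y2s/2

    Area-normalized shares are undefined (NaN) when the total area is zero.
    """
    q_L = model.q_L
    if q_L <= 0:
        raise DegenerateModelError("q_L must be positive to derive traits")
    q_S1 = 0.5 * model.q_x1s * model.q_y1s
    q_S2 = 0.5 * model.q_x2s * (model.q_y1s + model.q_y2s)
    q_S3 = 0.5 * model.q_x3s * model.q_y2s
    q_S = q_S1 + q_S2 + q_S3
    if q_S > 0:
        shares = (q_S1 / q_S, q_S2 / q_S, q_S3 / q_S)
    else:
        shares = (np.nan, np.nan, np.nan)
    return DerivedQuadrangleTraits(
        q_L=q_L,
        q_S1=q_S1, q_S2=q_S2, q_S3=q_S3, q_S=q_S,
        q_ym=q_S / q_L,
        q_x1ns=model.q_x1s / q_L,
        q_x2ns=model.q_x2s / q_L,
        q_x3ns=model.q_x3s / q_L,
        q_y1ns=model.q_y1s / q_L,
        q_y2ns=model.q_y2s / q_L,
        q_S1S=shares[0], q_S2S=shares[1], q_S3S=shares[2],
    )


def spike_density_index(ssc: float, sl: float) -> float:
    """Spike density index (SSC - 1) * 100 / SL, SL in mm (per decimetre)."""
    if sl <= 0:
        raise ValueError(f"SL must be positive, got {sl!r}")
    if ssc < 1:
        raise ValueError(f"SSC must be >= 1, got {ssc!r}")
    return (ssc - 1.0) * 100.0 / sl


def model_polyline(model: SymmetricQuadrangleModel) -> np.ndarray:
    """Closed (7, 2) vertex array of the mirrored quadrangle silhouette, mm.

    Runs base -> apex along the upper contour and back along the lower one,
    mirrored about the rachis axis (y = 0); first and last vertex coincide.
    """
    x1 = model.q_x1s
    x2 = model.q_x1s + model.q_x2s
    L = model.q_L
    return np.array([
        (0.0, 0.0),
        (x1, model.q_y1s),
        (x2, model.q_y2s),
        (L, 0.0),
        (x2, -model.q_y2s),
        (x1, -model.q_y1s),
        (0.0, 0.0),
    ])


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed or open polygon given as an (n, 2) array."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
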