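"""Trait-table serialization, run configuration and model visualization.

One canonical delimited dialect is used everywhere: comma-separated, dot
decimal, UTF-8, one header row whose trait columns carry the canonical
abbreviations (SL ... c_Ru).  Every table the package writes can be read
back unchanged.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import (
    ALL_TRAIT_NAMES,
    SymmetricQuadrangleModel,
    model_polyline,
)

__all__ = [
    "LABEL_COLUMNS",
    "TraitTableError",
    "RunConfig",
    "read_trait_table",
    "write_trait_table",
    "render_models",
]

LABEL_COLUMNS = ("plant", "species", "accession", "spike_type")

#: Manual length columns recorded in centimetres in field notebooks.
_CM_COLUMNS = ("SL", "SFW", "SSW")


class TraitTableError(ValueError):
    """A trait table file is structurally unusable."""


@dataclass
class RunConfig:
    """Configuration of one pipeline run; JSON round-trippable.

    ``scale_mm_per_px`` converts pixels to millimetres; ``background_rgb``
    is the backdrop colour; ``stem_side`` names the image border the stem
    points to; ``opening_radius_px`` strips awns; ``fit_grid`` is the
    breakpoint-search resolution; ``evaluation`` picks the LDA accuracy
    protocol.
    """

    scale_mm_per_px: float = 0.2
    background_rgb: List[int] = field(default_factory=lambda: [20, 60, 200])
    stem_side: str = "left"
    opening_radius_px: int = 5
    fit_grid: int = 60
    evaluation: str = "resubstitution"
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.stem_side not in ("left", "right", "top", "bottom"):
            raise ValueError(f"bad stem_side {self.stem_side!r}")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise TraitTableError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def read_trait_table(
    path: Union[str, Path], manual_units: str = "mm"
) -> pd.DataFrame:
    """Read a trait table CSV.

    ``manual_units="cm"`` flags the manual length columns (SL, SFW, SSW) as
    centimetre-valued; they are multiplied by 10 on ingest so all lengths
    are millimetres internally.  Unknown trait-like columns raise a warning;
    malformed numeric cells raise an error naming the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise TraitTableError(f"{path}: empty trait table") from exc
    if df.empty and not len(df.columns):
        raise TraitTableError(f"{path}: empty trait table")

    known = set(LABEL_COLUMNS) | set(ALL_TRAIT_NAMES)
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        warnings.warn(f"unknown columns kept as-is: {unknown}", stacklevel=2)

    for col in df.columns:
        if col in ALL_TRAIT_NAMES:
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna() & (df[col].str.strip() != "")
            if bad.any():
                line = int(bad.idxmax()) + 2  # header + 1-based
                raise TraitTableError(
                    f"{path}:{line}: malformed numeric value "
                    f"{df.loc[bad.idxmax(), col]!r} in column {col}"
                )
            df[col] = converted
    if manual_units == "cm":
        for col in _CM_COLUMNS:
            if col in df.columns:
                df[col] = df[col] * 10.0
    elif manual_units != "mm":
        raise ValueError(f"manual_units must be 'mm' or 'cm', got {manual_units!r}")
    return df


def write_trait_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a trait table CSV with label columns first, traits in canon order."""
    cols = [c for c in LABEL_COLUMNS if c in table.columns]
    cols += [c for c in ALL_TRAIT_NAMES if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def render_models(
    models: Sequence[SymmetricQuadrangleModel],
    out_prefix: Union[str, Path],
    mean_model: Optional[SymmetricQuadrangleModel] = None,
    vertical_exaggeration: float = 1.0,
    title: str = "",
) -> pd.DataFrame:
    """Draw quadrangle model polylines and export their coordinates.

    Individual models are drawn as thin lines; the group-mean model (built
    from per-parameter means when not supplied) is highlighted.  The
    vertical axis may be exaggerated for legibility — coordinates in the
    emitted CSV stay in true millimetres.  Writes ``<prefix>.png`` and
    ``<prefix>_coords.csv``; returns the coordinate table.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if mean_model is None and models:
        params = np.array([
            [m.q_x1s, m.q_x2s, m.q_x3s, m.q_y1s, m.q_y2s] for m in models
        ])
        mean_model = SymmetricQuadrangleModel(*params.mean(axis=0))

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    fig, ax = plt.subplots(figsize=(8, 3))
    rows = []
    for i, m in enumerate(models):
        poly = model_polyline(m)
        ax.plot(poly[:, 0], poly[:, 1] * vertical_exaggeration,
                color="steelblue", lw=0.7, alpha=0.7)
        for x, y in poly:
            rows.append({"model": i, "kind": "individual", "x_mm": x, "y_mm": y})
    if mean_model is not None:
        poly = model_polyline(mean_model)
        ax.plot(poly[:, 0], poly[:, 1] * vertical_exaggeration,
                color="crimson", lw=2.0)
        for x, y in poly:
            rows.append({"model": -1, "kind": "mean", "x_mm": x, "y_mm": y})
    ax.set_xlabel("rachis position, mm")
    ax.set_ylabel(
        "half-width, mm" if vertical_exaggeration == 1.0
        else f"half-width, mm (x{vertical_exaggeration:g})"
    )
    if title:
        ax.set_title(title)
    ax.axhline(0, color="0.6", lw=0.5)
    fig.tight_layout()
    fig.savefig(out_prefix.with_suffix(".png"), dpi=150)
    plt.close(fig)

    coords = pd.DataFrame(rows)
    coords.to_csv(out_prefix.parent / (out_prefix.name + "_coords.csv"), index=False)
    return coords
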