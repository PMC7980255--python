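"""Localization-table I/O, quality filters, and region-of-interest masking.

SMLM software (ThunderSTORM and friends) exports localizations as CSV tables
with one row per detected blinking event. This module reads those tables into
a :class:`LocalizationTable` (coordinates in nanometers internally), applies
per-point quality filters, masks by circular or polygonal ROIs, and reads and
writes the tool's own curve and label files.

Unit conventions: lengths are nm inside the package; areas and densities are
reported in μm² and μm⁻² (1 μm² = 10⁶ nm²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

__all__ = [
    "LocalizationTable",
    "CircleROI",
    "PolygonROI",
    "THUNDERSTORM_COLUMNS",
    "read_localizations",
    "filter_localizations",
    "apply_roi",
    "write_curve",
    "read_curve",
    "write_labels",
    "read_labels",
    "read_roi_file",
]

NM_PER_UM = 1000.0
NM2_PER_UM2 = 1e6

#: Default column mapping for ThunderSTORM CSV exports (all values in nm).
THUNDERSTORM_COLUMNS: dict[str, str] = {
    "x": "x [nm]",
    "y": "y [nm]",
    "z": "z [nm]",
    "frame": "frame",
    "uncertainty": "uncertainty [nm]",
    "intensity": "intensity [photon]",
}

_OPTIONAL_FIELDS = ("z", "frame", "uncertainty", "intensity")


class FormatError(ValueError):
    """Raised when an input file does not match the expected layout."""


@dataclass(frozen=True)
class LocalizationTable:
    """A set of 2D/3D localizations with coordinates in nm.

    Parameters
    ----------
    data
        DataFrame with mandatory float columns ``x`` and ``y`` (nm) and
        optional columns ``z`` (nm), ``frame`` (int), ``uncertainty`` (nm),
        ``intensity`` (photons).
    source_id
        Free-text provenance tag (typically the input file name).
    """

    data: pd.DataFrame
    source_id: str = ""

    def __post_init__(self) -> None:
        for col in ("x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"localization table lacks column {col!r}")
        xy = self.data[["x", "y"]].to_numpy(dtype=float)
        if xy.size and not np.isfinite(xy).all():
            raise ValueError("non-finite coordinates in localization table")
        if "uncertainty" in self.data.columns:
            unc = self.data["uncertainty"].to_numpy(dtype=float)
            if unc.size and np.nanmin(unc) < 0:
                raise ValueError("negative localization uncertainty")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def xy(self) -> np.ndarray:
        """(N, 2) float array of coordinates in nm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def has_z(self) -> bool:
        return "z" in self.data.columns

    @classmethod
    def from_xy(cls, xy: np.ndarray, source_id: str = "") -> "LocalizationTable":
        xy = np.asarray(xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError("expected an (N, 2) coordinate array")
        return cls(pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1]}), source_id)


@dataclass(frozen=True)
class CircleROI:
    """Circular region of interest; center and radius in nm."""

    cx: float
    cy: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("circle ROI radius must be positive")

    @property
    def area_um2(self) -> float:
        return math.pi * self.radius**2 / NM2_PER_UM2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        """Boundary-inclusive membership for (N, 2) nm coordinates."""
        d2 = (xy[:, 0] - self.cx) ** 2 + (xy[:, 1] - self.cy) ** 2
        return d2 <= self.radius**2


@dataclass(frozen=True)
class PolygonROI:
    """Simple-polygon region of interest; vertices in nm."""

    vertices: tuple[tuple[float, float], ...]
    _polygon: Polygon = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        poly = Polygon(self.vertices)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("polygon ROI must be simple with positive area")
        object.__setattr__(self, "_polygon", poly)

    @property
    def area_um2(self) -> float:
        return self._polygon.area / NM2_PER_UM2

    def contains(self, xy: np.ndarray) -> np.ndarray:
        # shapely covers() includes the boundary, matching the closed-ball
        # neighbor convention used everywhere else in the package
        return np.array(
            [self._polygon.covers(Point(p)) for p in xy], dtype=bool
        )


def read_localizations(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    unit: str = "nm",
) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Parameters
    ----------
    path
        CSV file with a header row.
    column_map
        Maps internal field names (``x``, ``y``, ``z``, ``frame``,
        ``uncertainty``, ``intensity``) to CSV column names. Defaults to the
        ThunderSTORM header preset; optional fields are used when present.
    unit
        Unit of the length-valued input columns: ``"nm"`` or ``"um"``.
        Coordinates are converted to nm.
    """
    path = Path(path)
    if column_map is None:
        column_map = THUNDERSTORM_COLUMNS
    if unit not in ("nm", "um"):
        raise ValueError(f"unknown unit {unit!r}: expected 'nm' or 'um'")
    scale = 1.0 if unit == "nm" else NM_PER_UM

    raw = pd.read_csv(path)
    for required in ("x", "y"):
        name = column_map.get(required)
        if name is None or name not in raw.columns:
            raise FormatError(
                f"required column {required!r} (mapped to {name!r}) "
                f"missing from {path.name}"
            )

    out: dict[str, np.ndarray] = {}
    length_fields = {"x", "y", "z", "uncertainty"}
    for fieldname in ("x", "y", *_OPTIONAL_FIELDS):
        name = column_map.get(fieldname)
        if name is None or name not in raw.columns:
            continue
        col = pd.to_numeric(raw[name], errors="coerce")
        bad = col.isna() & raw[name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric value in column {name!r} at data row {row}"
            )
        values = col.to_numpy(dtype=float)
        if fieldname in length_fields:
            values = values * scale
        out[fieldname] = values
    frame = pd.DataFrame(out)
    if "frame" in frame.columns:
        frame["frame"] = frame["frame"].astype("Int64")
    return LocalizationTable(frame, source_id=path.name)


def filter_localizations(
    table: LocalizationTable,
    max_uncertainty: float | None = None,
    z_range: tuple[float, float] | None = None,
    project_2d: bool = False,
) -> LocalizationTable:
    """Apply per-point quality filters, returning a new table.

    ``max_uncertainty`` keeps points with uncertainty strictly below the
    threshold (nm). ``z_range`` keeps points with z inside the closed
    interval (nm). ``project_2d`` drops the z column after filtering.
    """
    data = table.data
    keep = np.ones(len(data), dtype=bool)
    if max_uncertainty is not None:
        if "uncertainty" not in data.columns:
            raise ValueError("uncertainty filter requested but table has no uncertainty")
        keep &= data["uncertainty"].to_numpy(dtype=float) < max_uncertainty
    if z_range is not None:
        lo, hi = z_range
        if lo > hi:
            raise ValueError("z_range must be ordered (lo, hi)")
        if "z" not in data.columns:
            raise ValueError("z filter requested but table has no z column")
        z = data["z"].to_numpy(dtype=float)
        keep &= (z >= lo) & (z <= hi)
    out = data.loc[keep].reset_index(drop=True)
    if project_2d and "z" in out.columns:
        out = out.drop(columns="z")
    return replace(table, data=out)


def apply_roi(table: LocalizationTable, roi: CircleROI | PolygonROI) -> LocalizationTable:
    """Keep only localizations inside the ROI (boundary-inclusive)."""
    keep = roi.contains(table.xy)
    return replace(table, data=table.data.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# curve and label files
# ---------------------------------------------------------------------------

def write_curve(curve, path: str | Path) -> None:
    """Write a curve as a three-column TSV: ε [nm], Nc, Nc/Nloc.

    The total localization count is stored in a ``# Nloc=`` comment header so
    the file round-trips exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# Nloc={curve.nloc}\n")
        fh.write("# epsilon_nm\tNc\tNc_over_Nloc\n")
        for eps, nc, norm in zip(curve.grid.values, curve.nc, curve.normalized):
            fh.write(f"{float(eps)!r}\t{int(nc)}\t{float(norm)!r}\n")


def read_curve(path: str | Path):
    """Read a curve file written by :func:`write_curve`.

    Validates the structural invariants: Nc must be monotonically
    non-increasing in ε and bounded by [1, Nloc].
    """
    from .curves import EpsilonGrid, SuperStructureCurve

    path = Path(path)
    nloc: int | None = None
    eps: list[float] = []
    nc: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("Nloc="):
                    nloc = int(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path.name}:{lineno}: expected 3 columns")
            try:
                eps.append(float(parts[0]))
                nc.append(int(parts[1]))
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
    if nloc is None:
        raise FormatError(f"{path.name}: missing '# Nloc=' header")
    grid = EpsilonGrid.from_values(np.asarray(eps))
    return SuperStructureCurve(grid=grid, nc=np.asarray(nc, dtype=np.int64), nloc=nloc)


def write_labels(labels: Sequence[int], epsilon: float, path: str | Path) -> None:
    """Write per-point cluster labels at one ε as a two-column TSV."""
    labels = np.asarray(labels)
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# epsilon_nm={epsilon!r}\n")
        fh.write("# point_index\tcluster_id\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{int(lab)}\n")


def read_labels(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a labels file; returns (labels array, ε in nm)."""
    path = Path(path)
    epsilon: float | None = None
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("epsilon_nm="):
                    epsilon = float(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path.name}:{lineno}: expected 2 columns")
            rows.append((int(parts[0]), int(parts[1])))
    if epsilon is None:
        raise FormatError(f"{path.name}: missing '# epsilon_nm=' header")
    rows.sort()
    return np.array([lab for _, lab in rows], dtype=np.int64), epsilon


def read_roi_file(path: str | Path) -> list[CircleROI | PolygonROI]:
    """Read ROI definitions from a YAML file.

    Layout::

        unit: um            # or nm (applies to all lengths)
        circles:
          - {cx: 1.0, cy: 2.0, r: 1.5}
        polygons:
          - [[0, 0], [1, 0], [1, 1], [0, 1]]
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    unit = doc.get("unit", "nm")
    if unit not in ("nm", "um"):
        raise FormatError(f"unknown ROI unit {unit!r}")
    scale = 1.0 if unit == "nm" else NM_PER_UM
    rois: list[CircleROI | PolygonROI] = []
    for c in doc.get("circles", []) or []:
        rois.append(CircleROI(c["cx"] * scale, c["cy"] * scale, c["r"] * scale))
    for verts in doc.get("polygons", []) or []:
        rois.append(PolygonROI(tuple((x * scale, y * scale) for x, y in verts)))
    return rois
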