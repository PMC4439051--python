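"""Reading and writing case-control point datasets.

The canonical dataset format is a CSV with header row and columns
``x, y, label, region, birth_year, sex`` (label is ``case``/``control``,
case-insensitive); extra columns such as ``cause`` or ``match_id`` are kept
and can drive per-group analyses. GeoJSON FeatureCollections of Points with
the same fields as properties are also accepted. Study windows come from
GeoJSON Polygon files or WKT strings; if none is given, the convex hull of
the points is used and a warning issued.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .dstat import CaseControlPattern, STRATUM_COLUMNS
from .geometry import StudyWindow

__all__ = [
    "SchemaError",
    "read_window",
    "read_dataset",
    "read_dataset_frame",
    "frame_to_pattern",
    "write_dataset",
]

REQUIRED_COLUMNS = ("x", "y", "label")
LABEL_MAP = {"case": True, "control": False}


class SchemaError(ValueError):
    """The input file does not conform to the dataset schema."""


def read_window(source: Union[str, Path, dict], crs_tag: str = "") -> StudyWindow:
    """Study window from a GeoJSON polygon (path/dict/JSON text) or WKT string."""
    if isinstance(source, dict):
        return StudyWindow.from_geojson(source, crs_tag=crs_tag)
    text = str(source)
    stripped = text.lstrip()
    if not (stripped.startswith("{") or stripped.upper().startswith("POLYGON")):
        text = Path(text).read_text()
        stripped = text.lstrip()
    if stripped.startswith("{"):
        return StudyWindow.from_geojson(json.loads(text), crs_tag=crs_tag)
    return StudyWindow.from_wkt(text, crs_tag=crs_tag)


def _geojson_to_frame(obj: dict) -> pd.DataFrame:
    if obj.get("type") != "FeatureCollection":
        raise SchemaError("GeoJSON dataset must be a FeatureCollection of Points")
    rows = []
    for feat in obj["features"]:
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise SchemaError("every dataset feature must be a Point")
        row = dict(feat.get("properties") or {})
        row["x"], row["y"] = geom["coordinates"][:2]
        rows.append(row)
    return pd.DataFrame(rows)


def read_dataset_frame(path: Union[str, Path]) -> pd.DataFrame:
    """Load and validate the raw dataset table; malformed rows are dropped.

    Rows with non-numeric coordinates or unknown labels are rejected with a
    warning naming their file line numbers (header = line 1). Missing
    required columns raise :class:`SchemaError`.
    """
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        df = _geojson_to_frame(json.loads(path.read_text()))
        # line numbers are meaningless for GeoJSON; use feature order
        df.index = np.arange(len(df))
        lineno = df.index + 1
    else:
        df = pd.read_csv(path)
        lineno = df.index + 2  # header occupies line 1

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"dataset is missing required column(s): {missing}")

    x = pd.to_numeric(df["x"], errors="coerce")
    y = pd.to_numeric(df["y"], errors="coerce")
    label = df["label"].astype(str).str.strip().str.lower()
    bad = x.isna() | y.isna() | ~label.isin(LABEL_MAP)
    if bad.any():
        lines = ", ".join(str(int(l)) for l in np.asarray(lineno)[bad.to_numpy()])
        warnings.warn(
            f"rejected {int(bad.sum())} malformed row(s) at line(s): {lines}",
            stacklevel=2,
        )
        df = df[~bad.to_numpy()].copy()
        x, y, label = x[~bad], y[~bad], label[~bad]
    if df.empty:
        raise SchemaError("no valid rows in dataset")
    df["x"] = x.astype(float)
    df["y"] = y.astype(float)
    df["label"] = label.to_numpy()
    return df.reset_index(drop=True)


def frame_to_pattern(df: pd.DataFrame, window: Optional[StudyWindow] = None) -> CaseControlPattern:
    """Build a CaseControlPattern from a validated table."""
    if window is None:
        warnings.warn(
            "no study window supplied; using the convex hull of the points",
            stacklevel=2,
        )
        hull = MultiPoint(df[["x", "y"]].to_numpy()).convex_hull
        if hull.geom_type != "Polygon":
            raise SchemaError("cannot derive a window from collinear points")
        window = StudyWindow(hull)
    strata = None
    if all(c in df.columns for c in STRATUM_COLUMNS):
        keep = [c for c in df.columns if c not in ("x", "y", "label")]
        strata = df[keep].reset_index(drop=True)
    return CaseControlPattern(
        coords=df[["x", "y"]].to_numpy(dtype=float),
        is_case=(df["label"] == "case").to_numpy(),
        window=window,
        strata=strata,
    )


def read_dataset(
    path: Union[str, Path],
    window: Optional[Union[StudyWindow, str, Path, dict]] = None,
    group_by: Optional[Sequence[str]] = None,
):
    """Read a dataset into one pattern, or a dict of patterns keyed by group.

    ``group_by`` names columns (e.g. ``("cause", "region_group")``) whose
    distinct value combinations define independent analyses. Per-group row
    counts are reported via the returned patterns' sizes.
    """
    df = read_dataset_frame(path)
    if window is not None and not isinstance(window, StudyWindow):
        window = read_window(window)
    if not group_by:
        return frame_to_pattern(df, window)
    missing = [c for c in group_by if c not in df.columns]
    if missing:
        raise SchemaError(f"group_by column(s) not in dataset: {missing}")
    out = {}
    for key, sub in df.groupby(list(group_by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        out[key] = frame_to_pattern(sub.reset_index(drop=True), window)
    return out


def write_dataset(
    path: Union[str, Path],
    data: CaseControlPattern,
    extra: Optional[pd.DataFrame] = None,
    float_format: str = "%.3f",
) -> None:
    """Write a pattern to the canonical CSV schema (coordinates to mm precision)."""
    df = pd.DataFrame(
        {
            "x": data.coords[:, 0],
            "y": data.coords[:, 1],
            "label": np.where(data.is_case, "case", "control"),
        }
    )
    if data.strata is not None:
        df = pd.concat([df, data.strata.reset_index(drop=True)], axis=1)
    if extra is not None:
        df = pd.concat([df, extra.reset_index(drop=True)], axis=1)
    df.to_csv(path, index=False, float_format=float_format)
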