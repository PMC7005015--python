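"""Delimited-table readers/writers and density-map serialization.

All tables are comma-separated UTF-8 with a single header line and dot
decimals. Readers validate the header against the declared schema, type
every column, and report malformed rows with 1-based file line numbers.
Density maps round-trip losslessly as ``.npy`` arrays with a JSON sidecar
carrying the template extent and provenance metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityMap, FaceTemplate
from .errors import InvalidArgumentError, SchemaError
from .facegeom import FaceBox

__all__ = ["SCHEMAS", "read_table", "write_table",
           "read_gaze_table", "read_facebox_table", "read_speech_table",
           "read_trait_table", "read_fixation_table",
           "write_density_map", "read_density_map", "faceboxes_by_frame"]

#: column name -> type kind, per table
SCHEMAS: dict[str, dict[str, str]] = {
    # x/y may be NaN on invalid samples (blinks / track loss)
    "gaze": {"participant": "str", "task": "str", "t_ms": "float",
             "x_px": "floatna", "y_px": "floatna", "valid": "bool"},
    "facebox": {"participant": "str", "task": "str", "frame": "int",
                "x_tl": "float", "y_tl": "float", "x_tr": "float",
                "y_tr": "float", "x_br": "float", "y_br": "float",
                "x_bl": "float", "y_bl": "float"},
    "speech": {"participant": "str", "task": "str", "event": "str",
               "role": "str", "t_ms": "float"},
    "trait": {"participant": "str", "group": "str", "aq": "float",
              "lsas": "float"},
    "fixation": {"participant": "str", "task": "str", "t_start_ms": "float",
                 "t_end_ms": "float", "duration_ms": "float",
                 "x_px": "float", "y_px": "float",
                 "dispersion_deg": "float", "frame": "int"},
    "labeled_fixation": {"participant": "str", "task": "str",
                         "t_start_ms": "float", "t_end_ms": "float",
                         "duration_ms": "float", "x_px": "float",
                         "y_px": "float", "dispersion_deg": "float",
                         "frame": "int", "label": "str"},
}

_TRUE = {"true", "1", "1.0"}
_FALSE = {"false", "0", "0.0"}


def _convert(col: pd.Series, kind: str, name: str) -> pd.Series:
    if kind == "str":
        return col.astype(str)
    if kind == "bool":
        low = col.astype(str).str.strip().str.lower()
        bad = ~(low.isin(_TRUE) | low.isin(_FALSE))
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError(f"non-boolean flag {col[bad].iloc[0]!r}",
                              field=name, line=line)
        return low.isin(_TRUE)
    converted = pd.to_numeric(col, errors="coerce")
    if kind == "floatna":
        bad = converted.isna() & col.notna() \
            & (col.astype(str).str.strip().str.lower() != "nan")
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise SchemaError("unparsable numeric value "
                              f"{col[bad].iloc[0]!r}", field=name, line=line)
        return converted.astype(float)
    bad = converted.isna() & ~col.isna()
    if bad.any() or col.isna().any():
        mask = (bad | col.isna()).to_numpy()
        line = int(np.flatnonzero(mask)[0]) + 2
        raise SchemaError("unparsable numeric value "
                          f"{col[mask].iloc[0]!r}", field=name, line=line)
    if kind == "int":
        as_int = converted.astype(np.int64)
        if not np.allclose(as_int, converted):
            mask = (~np.isclose(converted, np.round(converted))).to_numpy()
            line = int(np.flatnonzero(mask)[0]) + 2
            raise SchemaError("non-integer value", field=name, line=line)
        return as_int
    return converted.astype(float)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a delimited table against a named schema."""
    if schema not in SCHEMAS:
        raise InvalidArgumentError(f"unknown schema {schema!r}")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing} in {path.name}",
                          field=missing[0])
    df = df[list(spec)]
    for name, kind in spec.items():
        df[name] = _convert(df[name], kind, name)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema: str) -> None:
    spec = SCHEMAS[schema]
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"missing columns {missing}", field=missing[0])
    df[list(spec)].to_csv(path, index=False)


def _check_time_order(df: pd.DataFrame, column: str) -> None:
    for (pid, task), g in df.groupby(["participant", "task"], sort=False):
        t = g[column].to_numpy(float)
        drops = np.flatnonzero(np.diff(t) < 0)
        if len(drops):
            line = int(g.index[drops[0] + 1]) + 2
            raise SchemaError(
                f"decreasing timestamps for {pid}/{task}",
                field=column, line=line)


def read_gaze_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, "gaze")
    _check_time_order(df, "t_ms")
    return df


def read_facebox_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, "facebox")


def read_speech_table(path: str | Path) -> pd.DataFrame:
    df = read_table(path, "speech")
    _check_time_order(df, "t_ms")
    return df


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, "trait")


def read_fixation_table(path: str | Path, labeled: bool = False) -> pd.DataFrame:
    return read_table(path, "labeled_fixation" if labeled else "fixation")


def faceboxes_by_frame(face_boxes: pd.DataFrame
                       ) -> dict[tuple[str, str], dict[int, FaceBox]]:
    """Index a face-box table as {(participant, task): {frame: FaceBox}}."""
    out: dict[tuple[str, str], dict[int, FaceBox]] = {}
    corners = [("x_tl", "y_tl"), ("x_tr", "y_tr"),
               ("x_br", "y_br"), ("x_bl", "y_bl")]
    for (pid, task), g in face_boxes.groupby(["participant", "task"],
                                             sort=False):
        frames = g["frame"].to_numpy(int)
        verts = np.stack([g[[cx, cy]].to_numpy(float) for cx, cy in corners],
                         axis=1)  # (n, 4, 2)
        # vectorized convexity check over all frames at once
        rolled1 = np.roll(verts, -1, axis=1)
        rolled2 = np.roll(verts, -2, axis=1)
        cross = ((rolled1[..., 0] - verts[..., 0])
                 * (rolled2[..., 1] - verts[..., 1])
                 - (rolled1[..., 1] - verts[..., 1])
                 * (rolled2[..., 0] - verts[..., 0]))
        bad = ((cross.min(axis=1) * cross.max(axis=1) <= 0)
               | (np.abs(cross) < 1e-12).any(axis=1))
        if bad.any():
            raise InvalidArgumentError(
                f"non-convex or degenerate face box for {pid}/{task} "
                f"at frame {int(frames[np.flatnonzero(bad)[0]])}")
        out[(pid, task)] = {
            int(f): FaceBox(frame=int(f), vertices=v, check=False)
            for f, v in zip(frames, verts)}
    return out


# ----------------------------------------------------------------------
# Density maps

def write_density_map(dmap: DensityMap, path: str | Path,
                      template: FaceTemplate | None = None) -> None:
    """Write a density map as ``.npy`` plus a ``.json`` sidecar.

    The map's dimensions must match the template grid.
    """
    template = template or FaceTemplate()
    expected = (template.height_px, template.width_px)
    if dmap.values.shape != expected:
        raise InvalidArgumentError(
            f"map shape {dmap.values.shape} != template {expected}")
    path = Path(path)
    np.save(path.with_suffix(".npy"), dmap.values)
    meta = {"participant": dmap.participant, "condition": dmap.condition,
            "missing": dmap.missing, "width_px": template.width_px,
            "height_px": template.height_px,
            "deg_per_px": template.deg_per_px,
            "extent_deg": list(template.extent_deg)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_density_map(path: str | Path) -> tuple[DensityMap, dict]:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    dmap = DensityMap(values, participant=meta.get("participant"),
                      condition=meta.get("condition"),
                      missing=bool(meta.get("missing", False)))
    return dmap, meta
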