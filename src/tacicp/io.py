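"""Readers and writers for the package's interchange formats.

The canonical format is JSON (contours are ragged, which JSON expresses
naturally); CSV is a flat convenience dialect.  Labeled point sets can be
exported to CSV or ASCII PLY for inspection in external viewers.

JSON schema (one file per image)::

    {
      "source_tag": str,
      "slice_spacing_mm": float,
      "slices": [
        {"z_mm": float,
         "contours": [
           {"label": "CCA|ICA|ECA|UNLABELED", "vertices": [[x, y], ...]}
         ]}
      ]
    }

CSV dialect: comment header lines ``# source_tag=...`` and
``# slice_spacing_mm=...`` followed by columns
``slice_index,z_mm,contour_index,label,vertex_index,x_mm,y_mm``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .exceptions import SchemaError, ValidationError
from .types import Contour2D, ContourStack, LabeledPointSet, VesselLabel

__all__ = ["read_contour_stack", "write_contour_stack", "export_pointset"]

_CSV_COLUMNS = ["slice_index", "z_mm", "contour_index", "label", "vertex_index", "x_mm", "y_mm"]


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format=")


def read_contour_stack(path: str | Path, format: str | None = None) -> ContourStack:
    """Read a validated :class:`ContourStack` from JSON or CSV.

    Raises :class:`SchemaError` naming the offending record on malformed
    input; all data-model invariants are re-checked on construction.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        return _read_json(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValidationError(f"unknown format {fmt!r}")


def write_contour_stack(stack: ContourStack, path: str | Path, format: str | None = None) -> None:
    """Write a stack losslessly; ``read_contour_stack`` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        _write_json(stack, path)
    elif fmt == "csv":
        _write_csv(stack, path)
    else:
        raise ValidationError(f"unknown format {fmt!r}")


def _read_json(path: Path) -> ContourStack:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as e:
        raise SchemaError(f"{path.name}: not valid JSON ({e})") from e
    if not isinstance(doc, dict) or "slices" not in doc:
        raise SchemaError(f"{path.name}: top level must be an object with 'slices'")
    contours: list[Contour2D] = []
    for i, sl in enumerate(doc["slices"]):
        try:
            z = float(sl["z_mm"])
            for j, c in enumerate(sl["contours"]):
                try:
                    contours.append(
                        Contour2D(z, np.asarray(c["vertices"], dtype=float),
                                  VesselLabel.from_name(c["label"]))
                    )
                except (ValidationError, KeyError, TypeError, ValueError) as e:
                    raise SchemaError(f"{path.name}: slice {i} contour {j}: {e}") from e
        except (KeyError, TypeError, ValueError) as e:
            if isinstance(e, SchemaError):
                raise
            raise SchemaError(f"{path.name}: slice {i}: {e}") from e
    try:
        return ContourStack(
            contours,
            slice_spacing_mm=float(doc.get("slice_spacing_mm", 0.0)),
            source_tag=str(doc.get("source_tag", "")),
        )
    except ValidationError as e:
        raise SchemaError(f"{path.name}: {e}") from e


def _write_json(stack: ContourStack, path: Path) -> None:
    doc = {
        "source_tag": stack.source_tag,
        "slice_spacing_mm": stack.slice_spacing_mm,
        "slices": [
            {
                "z_mm": z,
                "contours": [
                    {"label": c.label.name, "vertices": c.vertices.tolist()}
                    for c in group
                ],
            }
            for z, group in stack.slices()
        ],
    }
    path.write_text(json.dumps(doc, indent=1))


def _read_csv(path: Path) -> ContourStack:
    source_tag = ""
    spacing = 0.0
    rows: list[dict] = []
    with path.open(newline="") as fh:
        header: list[str] | None = None
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition("=")
                if key.strip() == "source_tag":
                    source_tag = val
                elif key.strip() == "slice_spacing_mm":
                    spacing = float(val)
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = fields
                if header != _CSV_COLUMNS:
                    raise SchemaError(f"{path.name}: bad CSV header {header}")
                continue
            rows.append(dict(zip(header, fields)))
    if header is None:
        raise SchemaError(f"{path.name}: empty CSV")
    # group rows into contours, preserving vertex order
    grouped: dict[tuple[int, int], dict] = {}
    for n, r in enumerate(rows):
        try:
            key = (int(r["slice_index"]), int(r["contour_index"]))
            grouped.setdefault(
                key, {"z": float(r["z_mm"]), "label": r["label"], "verts": []}
            )["verts"].append((int(r["vertex_index"]), float(r["x_mm"]), float(r["y_mm"])))
        except (KeyError, ValueError) as e:
            raise SchemaError(f"{path.name}: row {n}: {e}") from e
    contours = []
    for (si, ci), g in sorted(grouped.items()):
        verts = np.array([(x, y) for _, x, y in sorted(g["verts"])])
        try:
            contours.append(Contour2D(g["z"], verts, VesselLabel.from_name(g["label"])))
        except ValidationError as e:
            raise SchemaError(f"{path.name}: slice {si} contour {ci}: {e}") from e
    try:
        return ContourStack(contours, slice_spacing_mm=spacing, source_tag=source_tag)
    except ValidationError as e:
        raise SchemaError(f"{path.name}: {e}") from e


def _write_csv(stack: ContourStack, path: Path) -> None:
    with path.open("w", newline="") as fh:
        fh.write(f"# source_tag={stack.source_tag}\n")
        fh.write(f"# slice_spacing_mm={stack.slice_spacing_mm!r}\n")
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for si, (z, group) in enumerate(stack.slices()):
            for ci, c in enumerate(group):
                for vi, (x, y) in enumerate(c.vertices):
                    writer.writerow(
                        [si, repr(float(z)), ci, c.label.name, vi, repr(float(x)), repr(float(y))]
                    )


def export_pointset(ps: LabeledPointSet, path: str | Path, format: str | None = None) -> None:
    """Export a labeled point set to CSV (columns x,y,z,label) or ASCII PLY.

    PLY stores the label as a uchar property (CCA=0, ICA=1, ECA=2), so it
    rejects UNLABELED points.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = suffix if suffix in ("csv", "ply") else None
    if format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["x", "y", "z", "label"])
            for p, l in zip(ps.points, ps.labels):
                writer.writerow(
                    [repr(float(p[0])), repr(float(p[1])), repr(float(p[2])),
                     VesselLabel(int(l)).name]
                )
    elif format == "ply":
        if ps.has_unlabeled():
            raise ValidationError("PLY export requires resolved labels")
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(ps)}",
            "property float x",
            "property float y",
            "property float z",
            "property uchar label",
            "end_header",
        ]
        for p, l in zip(ps.points, ps.labels):
            lines.append(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f} {int(l)}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValidationError(f"unknown point-set export format {format!r}")


def import_pointset_csv(path: str | Path, role: str = "surface") -> LabeledPointSet:
    """Re-import a CSV written by :func:`export_pointset`."""
    path = Path(path)
    pts, labs = [], []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            pts.append([float(row["x"]), float(row["y"]), float(row["z"])])
            labs.append(int(VesselLabel.from_name(row["label"])))
    if not pts:
        raise SchemaError(f"{path.name}: no points")
    return LabeledPointSet(np.array(pts), np.array(labs), role)
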