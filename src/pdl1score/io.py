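"""Annotation and table I/O: ASAP XML polygons, LabelMe point JSON, CSV.

Coordinates are 0-based slide/patch pixels, origin top-left, x rightward,
y downward.
"""

from __future__ import annotations

import json
import logging
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "read_asap_annotations",
    "write_asap_annotations",
    "read_labelme_points",
    "write_labelme_points",
]

Polygon = list[tuple[float, float]]


class AnnotationParseError(ValueError):
    """Raised for malformed annotation files (message carries the location)."""


def read_asap_annotations(path: str | Path) -> list[Polygon]:
    """Read polygon annotations in the ASAP XML dialect.

    Expects ``Annotations/Annotation/Coordinates/Coordinate`` elements with
    ``X``, ``Y`` and ``Order`` attributes; vertices are returned sorted by
    ``Order`` so the drawn outline is preserved.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:  # exc.position = (line, column)
        line, col = exc.position
        raise AnnotationParseError(f"{path}: malformed XML at line {line}, column {col}: {exc.msg}") from exc
    polygons: list[Polygon] = []
    for ann in tree.getroot().iter("Annotation"):
        coords = ann.find("Coordinates")
        if coords is None:
            continue
        verts = []
        for c in coords.iter("Coordinate"):
            try:
                verts.append((int(c.get("Order", len(verts))), float(c.get("X")), float(c.get("Y"))))
            except (TypeError, ValueError) as exc:
                raise AnnotationParseError(f"{path}: Coordinate missing numeric X/Y in {ann.get('Name')}") from exc
        verts.sort(key=lambda v: v[0])
        if verts:
            polygons.append([(x, y) for _, x, y in verts])
    return polygons


def write_asap_annotations(path: str | Path, polygons: list[Polygon]) -> None:
    """Write polygons as ASAP XML (``Annotation Type="Polygon"`` elements)."""
    root = ET.Element("ASAP_Annotations")
    anns = ET.SubElement(root, "Annotations")
    for i, poly in enumerate(polygons):
        ann = ET.SubElement(
            anns,
            "Annotation",
            {"Name": f"Annotation {i}", "Type": "Polygon", "PartOfGroup": "None", "Color": "#F4FA58"},
        )
        coords = ET.SubElement(ann, "Coordinates")
        for order, (x, y) in enumerate(poly):
            ET.SubElement(coords, "Coordinate", {"Order": str(order), "X": repr(float(x)), "Y": repr(float(y))})
    ET.SubElement(root, "AnnotationGroups")
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_labelme_points(path: str | Path) -> np.ndarray:
    """Read cell-center points from a LabelMe JSON file.

    Only shapes with ``shape_type == "point"`` are kept; other shape types
    are skipped with a warning.  Returns an (n, 2) float array of (x, y).
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    if "shapes" not in doc:
        raise AnnotationParseError(f"{path}: missing 'shapes' key")
    pts = []
    skipped = 0
    for shape in doc["shapes"]:
        if shape.get("shape_type") != "point":
            skipped += 1
            continue
        x, y = shape["points"][0]
        pts.append((float(x), float(y)))
    if skipped:
        logger.warning("%s: skipped %d non-point shapes", path, skipped)
    return np.asarray(pts, dtype=float).reshape(-1, 2)


def write_labelme_points(
    path: str | Path,
    points: np.ndarray,
    image_size: tuple[int, int] | None = None,
    label: str = "cell",
) -> None:
    """Write (x, y) points as LabelMe point shapes."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    doc = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {"label": label, "points": [[float(x), float(y)]], "group_id": None, "shape_type": "point", "flags": {}}
            for x, y in points
        ],
        "imagePath": "",
        "imageData": None,
    }
    if image_size is not None:
        doc["imageWidth"], doc["imageHeight"] = int(image_size[0]), int(image_size[1])
    Path(path).write_text(json.dumps(doc, indent=2))
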