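"""Annotation I/O: imglab/Dlib XML dialect and the landmark CSV schema.

CSV schema (one row per landmark): ``image_id, index, name, x_px, y_px, role``
with real-valued pixel-center coordinates (x right, y down, (0,0) = center of
the top-left pixel).  The imglab dialect stores integer part coordinates; on
read they are taken as pixel-center integers, on write coordinates are
rounded to the nearest integer.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    N_LANDMARKS,
    ContractError,
    ImageSpace,
    LandmarkScheme,
    LandmarkSet,
)


class ParseError(ValueError):
    pass


def read_imglab_xml(
    path, space: Optional[ImageSpace] = None, scheme: Optional[LandmarkScheme] = None
) -> List[Tuple[str, LandmarkSet]]:
    """Read an imglab XML file into (image path, landmark set) pairs.

    Each ``<image>`` must hold exactly one ``<box>`` with exactly 23
    ``<part>`` elements whose numeric names map to landmark indices
    (``name='00'`` -> L1 ... ``name='22'`` -> L23).
    """
    scheme = scheme or LandmarkScheme.default()
    space = space or ImageSpace(1200, 1200)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ParseError(f"{path}: malformed XML: {exc}") from exc
    images = tree.getroot().find("images")
    if images is None:
        raise ParseError(f"{path}: no <images> element")
    out: List[Tuple[str, LandmarkSet]] = []
    for image in images.findall("image"):
        file = image.get("file", "<unknown>")
        boxes = image.findall("box")
        if len(boxes) != 1:
            raise ParseError(f"{path}: image {file!r} has {len(boxes)} boxes, expected 1")
        box = boxes[0]
        parts = box.findall("part")
        if len(parts) != N_LANDMARKS:
            raise ParseError(
                f"{path}: image {file!r} box has {len(parts)} parts, expected {N_LANDMARKS}"
            )
        coords = np.full((N_LANDMARKS, 2), np.nan)
        for part in parts:
            try:
                idx = int(part.get("name"))
                x = float(part.get("x"))
                y = float(part.get("y"))
            except (TypeError, ValueError) as exc:
                raise ParseError(f"{path}: image {file!r}: bad part attributes") from exc
            if not 0 <= idx < N_LANDMARKS:
                raise ParseError(f"{path}: image {file!r}: part name {idx} out of range")
            coords[idx] = (x, y)
        if np.any(np.isnan(coords)):
            raise ParseError(f"{path}: image {file!r}: duplicate or missing part indices")
        out.append((file, LandmarkSet(scheme, space, coords, role="ground_truth")))
    return out


def write_imglab_xml(path, entries: Sequence[Tuple[str, LandmarkSet]]) -> None:
    """Write (image path, landmark set) pairs in the imglab XML dialect."""
    root = ET.Element("dataset")
    ET.SubElement(root, "name").text = "cephalo landmark annotations"
    comment = ET.SubElement(root, "comment")
    comment.text = (
        "coordinates: integer pixels, pixel-center model, origin top-left, y down"
    )
    images = ET.SubElement(root, "images")
    for file, ls in entries:
        image = ET.SubElement(images, "image", file=str(file))
        xs, ys = ls.coords[:, 0], ls.coords[:, 1]
        left, top = int(np.floor(xs.min())), int(np.floor(ys.min()))
        box = ET.SubElement(
            image,
            "box",
            top=str(top),
            left=str(left),
            width=str(int(np.ceil(xs.max())) - left + 1),
            height=str(int(np.ceil(ys.max())) - top + 1),
        )
        for i, (x, y) in enumerate(ls.coords):
            ET.SubElement(
                box, "part", name=f"{i:02d}", x=str(int(round(x))), y=str(int(round(y)))
            )
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode")


def write_landmark_csv(path, entries: Sequence[Tuple[str, LandmarkSet]]) -> None:
    rows = []
    for image_id, ls in entries:
        for i in range(1, N_LANDMARKS + 1):
            x, y = ls.point(i)
            rows.append(
                {
                    "image_id": image_id,
                    "index": i,
                    "name": ls.scheme.name_of(i),
                    "x_px": x,
                    "y_px": y,
                    "role": ls.role,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmark_csv(
    path,
    space: Optional[ImageSpace] = None,
    scheme: Optional[LandmarkScheme] = None,
    role: Optional[str] = None,
) -> List[Tuple[str, LandmarkSet]]:
    """Read the landmark CSV schema; optionally filter by role."""
    scheme = scheme or LandmarkScheme.default()
    space = space or ImageSpace(1200, 1200)
    df = pd.read_csv(path)
    required = {"image_id", "index", "x_px", "y_px", "role"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if role is not None:
        df = df[df["role"] == role]
    out = []
    for image_id, group in df.groupby("image_id", sort=False):
        for role_value, sub in group.groupby("role", sort=False):
            if len(sub) != N_LANDMARKS:
                raise ParseError(
                    f"{path}: image {image_id!r} role {role_value!r} has {len(sub)} rows"
                )
            coords = np.full((N_LANDMARKS, 2), np.nan)
            for _, row in sub.iterrows():
                coords[int(row["index"]) - 1] = (row["x_px"], row["y_px"])
            if np.any(np.isnan(coords)):
                raise ParseError(f"{path}: image {image_id!r}: missing indices")
            out.append((str(image_id), LandmarkSet(scheme, space, coords, role=str(role_value))))
    return out
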