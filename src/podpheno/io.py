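"""Reading and writing the package's on-disk formats.

Images are PNG/TIFF/JPEG rasters (via imageio); detection ground truth is
Pascal-VOC-style XML; predictions and boxes travel as CSV with columns
``x1,y1,x2,y2[,confidence]``; contours as CSV of ``x,y``; trait/weight
tables as CSV with the canonical trait columns.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .boxes import Box
from .preprocessing import Contour
from .yield_model import TRAIT_COLUMNS

__all__ = [
    "read_image",
    "write_image",
    "read_boxes_csv",
    "write_boxes_csv",
    "read_voc_xml",
    "write_voc_xml",
    "read_contour_csv",
    "write_contour_csv",
    "read_trait_table",
    "write_trait_table",
]


def read_image(path: str | Path) -> np.ndarray:
    return iio.imread(Path(path))


def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(image))


def read_boxes_csv(path: str | Path) -> list[Box]:
    """CSV of x1,y1,x2,y2[,confidence] -> boxes (confidence kept if present)."""
    df = pd.read_csv(path)
    required = ["x1", "y1", "x2", "y2"]
    if any(c not in df.columns for c in required):
        raise ValueError(f"boxes CSV needs columns {required}, got {list(df.columns)}")
    has_conf = "confidence" in df.columns
    return [
        Box(
            r.x1, r.y1, r.x2, r.y2,
            confidence=float(r.confidence) if has_conf else None,
        )
        for r in df.itertuples()
    ]


def write_boxes_csv(path: str | Path, boxes: list[Box]) -> None:
    rows = []
    any_conf = any(b.confidence is not None for b in boxes)
    for b in boxes:
        row = {"x1": b.x1, "y1": b.y1, "x2": b.x2, "y2": b.y2}
        if any_conf:
            row["confidence"] = b.confidence
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_voc_xml(path: str | Path) -> list[Box]:
    """Ground-truth boxes from a Pascal-VOC annotation file."""
    root = ET.parse(Path(path)).getroot()
    boxes = []
    for obj in root.iter("object"):
        bb = obj.find("bndbox")
        if bb is None:
            continue
        boxes.append(
            Box(
                float(bb.findtext("xmin")),
                float(bb.findtext("ymin")),
                float(bb.findtext("xmax")),
                float(bb.findtext("ymax")),
            )
        )
    return boxes


def write_voc_xml(
    path: str | Path,
    boxes: list[Box],
    image_size: tuple[int, int],
    name: str = "pod",
) -> None:
    """Write boxes as a Pascal-VOC annotation (single class, default 'pod')."""
    rows, cols = image_size
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = Path(path).stem
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(cols)
    ET.SubElement(size, "height").text = str(rows)
    ET.SubElement(size, "depth").text = "1"
    for b in boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = name
        bb = ET.SubElement(obj, "bndbox")
        ET.SubElement(bb, "xmin").text = f"{b.x1:g}"
        ET.SubElement(bb, "ymin").text = f"{b.y1:g}"
        ET.SubElement(bb, "xmax").text = f"{b.x2:g}"
        ET.SubElement(bb, "ymax").text = f"{b.y2:g}"
    ET.ElementTree(root).write(Path(path), encoding="unicode")


def read_contour_csv(path: str | Path) -> Contour:
    df = pd.read_csv(path)
    return Contour(points=df[["x", "y"]].to_numpy(dtype=float))


def write_contour_csv(path: str | Path, contour: Contour) -> None:
    pd.DataFrame(contour.points, columns=["x", "y"]).to_csv(path, index=False)


def read_trait_table(path: str | Path, require_weight: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path)
    needed = TRAIT_COLUMNS + (["weight_g"] if require_weight else [])
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"trait table missing columns {missing}")
    return df


def write_trait_table(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False)
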