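"""VGG Image Annotator (VIA 2.x) project I/O and rating-table export.

The VIA 2 project JSON keeps a map of image entries (either at the top level
or under ``_via_img_metadata``); each entry carries ``filename``,
``file_attributes`` and a list of regions whose ``shape_attributes`` hold the
geometry (``polygon`` for wound borders, ``polyline`` for halving lines).
The assessor id and analysis round ride along in ``region_attributes`` so a
whole multi-assessor round fits in one project file; plain single-assessor
exports parse the same way via the defaults.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line
from skimage.segmentation import find_boundaries

from .errors import (
    IncompleteDesignError,
    MissingReferenceError,
    ViaSchemaError,
)
from .geometry import (
    BinaryMask,
    HalvingLine,
    WoundOutline,
    halve,
    rasterize_outlines,
    split_by_line,
)

logger = logging.getLogger(__name__)

RATING_COLUMNS = [
    "image_id",
    "assessor_id",
    "round",
    "source",
    "fraction_side1",
    "abs_deviation",
]


@dataclass
class AnnotationRecord:
    """All regions one assessor drew on one image in one round."""

    image_id: str
    assessor_id: str
    round: int
    polygons: list[np.ndarray] = field(default_factory=list)
    polylines: list[np.ndarray] = field(default_factory=list)
    filename: str = ""
    image_size: tuple[int, int] | None = None


def _load_doc(doc) -> dict:
    if isinstance(doc, dict):
        return doc
    if isinstance(doc, Path):
        text = doc.read_text()
    elif isinstance(doc, str):
        text = Path(doc).read_text() if not doc.lstrip().startswith("{") else doc
    else:
        raise ViaSchemaError(f"unsupported VIA document type: {type(doc)!r}")
    try:
        return json.loads(text)
    except json.JSONDecodeError as exc:
        raise ViaSchemaError(f"malformed VIA JSON: {exc}") from exc


def _image_entries(data: dict) -> dict:
    meta = data.get("_via_img_metadata", data)
    if not isinstance(meta, dict):
        raise ViaSchemaError("VIA project must be a JSON object of image entries")
    return {
        k: v
        for k, v in meta.items()
        if isinstance(v, dict) and not k.startswith("_via")
    }


def read_via_project(
    doc,
    default_assessor: str = "A1",
    default_round: int = 1,
    image_sizes: dict | None = None,
) -> list[AnnotationRecord]:
    """Parse a VIA 2.x project into annotation records, in document order.

    One record per (image, assessor, round) group; the assessor/round come
    from each region's ``region_attributes`` with the given fallbacks.
    ``image_sizes`` optionally maps image ids (or filenames) to
    (width, height) when the project's ``file_attributes`` lack them.
    """
    data = _load_doc(doc)
    records: dict[tuple, AnnotationRecord] = {}
    for key, entry in _image_entries(data).items():
        filename = entry.get("filename", key)
        image_id = Path(filename).stem
        fa = entry.get("file_attributes", {}) or {}
        size = None
        if "width" in fa and "height" in fa:
            size = (int(fa["width"]), int(fa["height"]))
        elif image_sizes is not None:
            size = image_sizes.get(image_id) or image_sizes.get(filename)
            size = tuple(size) if size is not None else None
        for ri, region in enumerate(entry.get("regions", [])):
            sa = region.get("shape_attributes", {}) or {}
            ra = region.get("region_attributes", {}) or {}
            name = sa.get("name")
            if name not in ("polygon", "polyline"):
                logger.warning(
                    "skipping unsupported region type %r (image %s, region %d)",
                    name,
                    image_id,
                    ri,
                )
                continue
            xs, ys = sa.get("all_points_x"), sa.get("all_points_y")
            if xs is None or ys is None or len(xs) != len(ys):
                raise ViaSchemaError(
                    f"region {ri} of image {image_id}: "
                    "mismatched or missing all_points_x/all_points_y"
                )
            pts = np.column_stack([xs, ys]).astype(float)
            assessor = str(ra.get("assessor", default_assessor))
            rnd = int(ra.get("round", default_round))
            k = (image_id, assessor, rnd)
            rec = records.get(k)
            if rec is None:
                rec = records[k] = AnnotationRecord(
                    image_id=image_id,
                    assessor_id=assessor,
                    round=rnd,
                    filename=filename,
                    image_size=size,
                )
            if name == "polygon":
                if len(pts) < 3:
                    raise ViaSchemaError(
                        f"region {ri} of image {image_id}: "
                        "polygon needs at least 3 vertices"
                    )
                rec.polygons.append(pts)
            else:
                if len(pts) < 2:
                    raise ViaSchemaError(
                        f"region {ri} of image {image_id}: "
                        "polyline needs at least 2 points"
                    )
                rec.polylines.append(pts)
    return list(records.values())


def write_via_line(
    doc,
    image_id: str,
    line: HalvingLine,
    assessor_id: str | None = None,
    round: int | None = None,
) -> dict:
    """Return a copy of the project with the line appended as a polyline region.

    Raises :class:`MissingReferenceError` if no image entry matches
    ``image_id`` (by filename stem or entry key).
    """
    data = copy.deepcopy(_load_doc(doc))
    meta = data.get("_via_img_metadata", data)
    region_attributes: dict = {"source": line.source}
    if assessor_id is not None:
        region_attributes["assessor"] = assessor_id
    if round is not None:
        region_attributes["round"] = round
    for key, entry in _image_entries(data).items():
        filename = entry.get("filename", key)
        if Path(filename).stem == image_id or key == image_id:
            entry.setdefault("regions", []).append(
                {
                    "shape_attributes": {
                        "name": "polyline",
                        "all_points_x": [float(p[0]) for p in line.endpoints],
                        "all_points_y": [float(p[1]) for p in line.endpoints],
                    },
                    "region_attributes": region_attributes,
                }
            )
            return data
    raise MissingReferenceError(f"no image entry matches {image_id!r}")


def render_overlay(
    image: np.ndarray,
    mask: BinaryMask,
    line: HalvingLine | None = None,
    contour_color=(0, 255, 0),
    line_color=(255, 40, 40),
) -> np.ndarray:
    """Copy of the image with the wound contour and the halving line drawn."""
    img = np.asarray(image)
    if img.shape[:2] != mask.grid.shape:
        raise ValueError(
            f"image shape {img.shape[:2]} does not match mask {mask.grid.shape}"
        )
    out = img.copy()
    if out.ndim == 2:
        out = np.stack([out] * 3, axis=-1)
    h, w = mask.grid.shape
    out[find_boundaries(mask.grid, mode="inner")] = contour_color
    if line is not None:
        pts = np.round(line.endpoints).astype(int)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(y0, x0, y1, x1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            out[rr[keep], cc[keep]] = line_color
    return out


# ---------------------------------------------------------------------------
# rating tables
# ---------------------------------------------------------------------------


def export_rating_table(rows, path=None) -> pd.DataFrame:
    """Build (and optionally write) the tidy rating table.

    One row per (image, assessor, round, source); duplicates are an error, as
    is any abs_deviation inconsistent with its fraction.
    """
    df = pd.DataFrame(list(rows), columns=RATING_COLUMNS)
    key = ["image_id", "assessor_id", "round", "source"]
    if df.duplicated(subset=key).any():
        dupes = df[df.duplicated(subset=key, keep=False)][key]
        raise ViaSchemaError(f"duplicate rating rows:\n{dupes.to_string(index=False)}")
    if len(df) and not np.allclose(
        df["abs_deviation"], (df["fraction_side1"] - 50.0).abs(), atol=1e-9
    ):
        raise ViaSchemaError("abs_deviation must equal |fraction_side1 - 50|")
    df = df.sort_values(key, kind="stable").reset_index(drop=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_rating_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise ViaSchemaError(f"rating table missing columns: {sorted(missing)}")
    return df


def evaluate_study(
    round1: list[AnnotationRecord],
    round2: list[AnnotationRecord] | None = None,
    image_sizes: dict | None = None,
) -> pd.DataFrame:
    """Evaluate a two-round annotation study into a rating table.

    For each assessor, the round-1 outline that assessor drew defines 100%
    of the wound area; the algorithm's split and both rounds' manual lines
    are all evaluated against that per-assessor mask.  Algorithm rows are
    emitted once per (image, assessor) with round = 1.
    """
    rows = []
    masks: dict[tuple[str, str], BinaryMask] = {}
    for rec in round1:
        if not rec.polygons:
            continue
        size = rec.image_size or (
            image_sizes.get(rec.image_id) if image_sizes else None
        )
        if size is None:
            raise MissingReferenceError(
                f"no image size known for {rec.image_id!r}"
            )
        outlines = [WoundOutline(p, tuple(size)) for p in rec.polygons]
        mask = rasterize_outlines(outlines)
        masks[(rec.image_id, rec.assessor_id)] = mask
        outcome = halve(mask)
        rows.append(
            dict(
                image_id=rec.image_id,
                assessor_id=rec.assessor_id,
                round=1,
                source="algorithm",
                fraction_side1=outcome.split.fraction_side1,
                abs_deviation=outcome.split.abs_deviation,
            )
        )
        if rec.polylines:
            split = split_by_line(mask, HalvingLine(rec.polylines[0], "manual"))
            rows.append(
                dict(
                    image_id=rec.image_id,
                    assessor_id=rec.assessor_id,
                    round=1,
                    source="manual",
                    fraction_side1=split.fraction_side1,
                    abs_deviation=split.abs_deviation,
                )
            )
    for rec in round2 or []:
        if not rec.polylines:
            continue
        mask = masks.get((rec.image_id, rec.assessor_id))
        if mask is None:
            raise MissingReferenceError(
                f"round-2 line for ({rec.image_id}, {rec.assessor_id}) has no "
                "governing round-1 outline"
            )
        split = split_by_line(mask, HalvingLine(rec.polylines[0], "manual"))
        rows.append(
            dict(
                image_id=rec.image_id,
                assessor_id=rec.assessor_id,
                round=2,
                source="manual",
                fraction_side1=split.fraction_side1,
                abs_deviation=split.abs_deviation,
            )
        )
    return export_rating_table(rows)


def check_complete(df: pd.DataFrame, images, assessors, rounds=(1, 2)) -> None:
    """Raise with an explicit missing-cell listing if the design is incomplete."""
    have = {
        (r.image_id, r.assessor_id, r.round)
        for r in df[df.source == "manual"].itertuples()
    }
    missing = [
        (i, a, r)
        for i in images
        for a in assessors
        for r in rounds
        if (i, a, r) not in have
    ]
    if missing:
        raise IncompleteDesignError(
            "missing manual ratings for cells: " + ", ".join(map(str, missing))
        )
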