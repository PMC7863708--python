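"""Reading and writing the file formats the tool touches.

Images are 8-bit grayscale Windows bitmaps (the format ultrasound consoles
export); 24-bit BMPs are accepted and collapsed to gray with Rec.601 luma
weights, and PNG is accepted as a courtesy input.  Regions of interest are
small JSON files holding a label ("fascia" or "kidney") and an ordered
vertex list, because segmentation in this workflow is manual: the contract
is vertices in, mask out.  Study manifests and per-image results are plain
CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image, UnidentifiedImageError

from .errors import FormatError, ValidationError

ROI_LABELS = ("fascia", "kidney")
SIDES = ("left", "right")
METHODS = ("random", "standardized")

#: Rec.601 luma weights used to collapse 24-bit color to gray.
_LUMA = np.array([0.299, 0.587, 0.114])

MANIFEST_COLUMNS = [
    "patient_id",
    "side",
    "physician_id",
    "device_id",
    "method",
    "normalized",
    "image_path",
    "fascia_roi_path",
    "kidney_roi_path",
]


def _round_half_away(x: np.ndarray | float) -> np.ndarray | float:
    """Round half away from zero (values here are non-negative)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


@dataclass
class GrayImage:
    """An 8-bit intensity raster with acquisition provenance.

    ``pixels`` is a ``(height, width)`` uint8 array in row-major order;
    ``source_id`` is an opaque tag (usually the originating file path).
    """

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise ValidationError(
                f"image must be a non-empty 2-D raster, got shape {arr.shape}"
            )
        if arr.dtype != np.uint8:
            if np.any(arr < 0) or np.any(arr > 255):
                raise ValidationError("intensities must lie in [0, 255]")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValidationError("intensities must be integers")
            arr = arr.astype(np.uint8)
        self.pixels = arr

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def height(self) -> int:
        return self.pixels.shape[0]


@dataclass
class PolygonROI:
    """A manually drawn closed contour.

    Vertices are ``(x, y)`` pixel coordinates, 0-based, origin at the
    top-left, x rightward and y downward.  The polygon is implicitly
    closed (last vertex connects back to the first).
    """

    label: str
    vertices: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValidationError(
                f"unknown ROI label {self.label!r}; expected one of {ROI_LABELS}"
            )
        verts = [(float(x), float(y)) for x, y in self.vertices]
        if len(verts) < 3:
            raise ValidationError(
                f"polygon needs at least 3 vertices, got {len(verts)}"
            )
        self.vertices = verts

    def check_within(self, width: int, height: int) -> None:
        """Raise if any vertex falls outside a ``width``x``height`` image."""
        for x, y in self.vertices:
            if not (0 <= x <= width - 1 and 0 <= y <= height - 1):
                raise ValidationError(
                    f"vertex ({x}, {y}) outside image bounds {width}x{height}"
                )


@dataclass
class AcquisitionRecord:
    """One image's study tags: who acquired what, how, and where it lives."""

    patient_id: str
    side: str
    physician_id: str
    device_id: str
    method: str
    normalized: bool
    image_path: str
    fascia_roi_path: str
    kidney_roi_path: str

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValidationError(f"side must be one of {SIDES}, got {self.side!r}")
        if self.method not in METHODS:
            raise ValidationError(
                f"method must be one of {METHODS}, got {self.method!r}"
            )
        self.normalized = bool(self.normalized)

    @property
    def category(self) -> str:
        """One of random, standardized, random-normalized, standardized-normalized."""
        return self.method + ("-normalized" if self.normalized else "")


def read_gray_bmp(path: str | Path) -> GrayImage:
    """Read a BMP (or PNG) file as an 8-bit grayscale image.

    8-bit gray or gray-palette files are read directly; 24-bit color is
    collapsed per pixel with Rec.601 weights (0.299 R + 0.587 G + 0.114 B)
    rounded half away from zero.  Other bit depths raise
    :class:`FormatError` naming the offending mode.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            mode = im.mode
            if mode == "L":
                arr = np.asarray(im, dtype=np.uint8)
            elif mode in ("P", "RGB"):
                rgb = np.asarray(im.convert("RGB"), dtype=float)
                if np.all(rgb[..., 0] == rgb[..., 1]) and np.all(
                    rgb[..., 1] == rgb[..., 2]
                ):
                    arr = rgb[..., 0].astype(np.uint8)
                else:
                    arr = _round_half_away(rgb @ _LUMA)
                    arr = np.clip(arr, 0, 255).astype(np.uint8)
            else:
                raise FormatError(
                    f"unsupported image mode {mode!r} in {path} "
                    "(expected 8-bit gray/palette or 24-bit RGB)"
                )
    except UnidentifiedImageError as exc:
        raise FormatError(f"{path} is not a readable image: {exc}") from exc
    except OSError as exc:
        raise OSError(f"cannot read image {path}: {exc}") from exc
    return GrayImage(pixels=arr, source_id=str(path))


def write_gray_bmp(image: GrayImage, path: str | Path) -> None:
    """Write an 8-bit grayscale BMP; round-trips losslessly with
    :func:`read_gray_bmp`."""
    path = Path(path)
    try:
        Image.fromarray(image.pixels, mode="L").save(path, format="BMP")
    except OSError as exc:
        raise OSError(f"cannot write image {path}: {exc}") from exc


def write_color_bmp(rgb: np.ndarray, path: str | Path) -> None:
    """Write an ``(H, W, 3)`` uint8 raster as a 24-bit BMP."""
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError(f"expected (H, W, 3) color raster, got {rgb.shape}")
    Image.fromarray(rgb.astype(np.uint8), mode="RGB").save(Path(path), format="BMP")


def read_roi(path: str | Path) -> PolygonROI:
    """Read a polygon ROI from its JSON file.

    Schema: ``{"label": "fascia"|"kidney", "vertices": [[x, y], ...]}``.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    if not isinstance(payload, Mapping) or "label" not in payload or "vertices" not in payload:
        raise ValidationError(f"{path}: ROI file must have 'label' and 'vertices'")
    return PolygonROI(label=payload["label"], vertices=payload["vertices"])


def write_roi(roi: PolygonROI, path: str | Path) -> None:
    """Write a polygon ROI as JSON (inverse of :func:`read_roi`)."""
    payload = {"label": roi.label, "vertices": [[x, y] for x, y in roi.vertices]}
    Path(path).write_text(json.dumps(payload, indent=1))


_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _parse_bool(value: object) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a boolean")


def read_manifest(path: str | Path) -> list[AcquisitionRecord]:
    """Read an acquisition manifest CSV into a list of records.

    The manifest has one row per stored image with the columns in
    :data:`MANIFEST_COLUMNS`; every missing column is a schema error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} is missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            AcquisitionRecord(
                patient_id=row["patient_id"],
                side=row["side"],
                physician_id=row["physician_id"],
                device_id=row["device_id"],
                method=row["method"],
                normalized=_parse_bool(row["normalized"]),
                image_path=row["image_path"],
                fascia_roi_path=row["fascia_roi_path"],
                kidney_roi_path=row["kidney_roi_path"],
            )
        )
    return records


def write_manifest(records: Iterable[AcquisitionRecord], path: str | Path) -> None:
    """Write acquisition records as a manifest CSV (inverse of
    :func:`read_manifest`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "side": r.side,
                "physician_id": r.physician_id,
                "device_id": r.device_id,
                "method": r.method,
                "normalized": str(bool(r.normalized)).lower(),
                "image_path": r.image_path,
                "fascia_roi_path": r.fascia_roi_path,
                "kidney_roi_path": r.kidney_roi_path,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def write_results_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write per-image analysis rows (identifiers, GSM, one percentage per
    brightness band) as CSV with a stable column order.

    All rows must share one key set; numeric values are written with at
    least 4 significant digits.  With zero rows a header-only file is
    written (``columns`` supplies the header when no row can).
    """
    path = Path(path)
    if len(rows) == 0:
        pd.DataFrame(columns=list(columns or [])).to_csv(path, index=False)
        return
    keys = list(columns) if columns is not None else list(rows[0].keys())
    keyset = set(keys)
    for i, row in enumerate(rows):
        if set(row.keys()) != keyset:
            raise ValidationError(
                f"row {i} keys {sorted(row.keys())} differ from row 0 keys {sorted(keys)}"
            )
    df = pd.DataFrame(list(rows), columns=keys)
    df.to_csv(path, index=False, float_format="%.6g")
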