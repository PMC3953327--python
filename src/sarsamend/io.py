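"""Raster and report I/O.

Grayscale images are read from 8/16-bit PNG or TIFF and rescaled to
[0, 1]; boundary maps are written 0/255 and read back with any nonzero
pixel treated as marked. Metric reports serialise to JSON plus a TSV
table with one row per image and a final macro-average row.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .metrics import MacroReport, MetricReport

__all__ = [
    "FormatError",
    "read_gray",
    "read_boundary",
    "write_boundary",
    "write_labels",
    "write_report",
]


class FormatError(ValueError):
    """Unreadable or unsupported image file."""


def _load_array(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            arr = tifffile.imread(path)
            if arr.ndim == 3 and arr.shape[0] > 4:  # multi-page stack
                raise FormatError(f"multi-page TIFF not supported: {path}")
        else:
            with Image.open(path) as im:
                if getattr(im, "n_frames", 1) > 1:
                    raise FormatError(f"multi-frame image not supported: {path}")
                arr = np.asarray(im)
    except FormatError:
        raise
    except Exception as exc:
        raise FormatError(f"cannot read image {path}: {exc}") from exc
    return arr


def _to_gray(arr: np.ndarray, path) -> np.ndarray:
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
        else:
            raise FormatError(f"unsupported image layout {arr.shape} in {path}")
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D image in {path}, got shape {arr.shape}")
    return arr


def read_gray(path) -> np.ndarray:
    """Read a grayscale image, rescaled to [0, 1] by its dtype range."""
    arr = _to_gray(_load_array(path), path)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.size and arr.max() > 1.0:  # integer-coded without dtype hint
        arr = arr / arr.max()
    return arr


def read_boundary(path) -> np.ndarray:
    """Read a binary boundary map: any nonzero pixel is marked."""
    return _to_gray(_load_array(path), path) != 0


def write_boundary(boundary_map, path) -> None:
    """Write a boundary map as 8-bit single-channel PNG/TIFF (255 = marked)."""
    path = Path(path)
    arr = ((np.asarray(boundary_map) != 0) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def write_labels(labels, path) -> None:
    """Write a label image as 16-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels).astype(np.uint16))


def write_report(reports: dict[str, MetricReport], macro: MacroReport, path) -> None:
    """Serialise per-image reports plus the macro row as JSON and TSV.

    ``path`` names the JSON file; the TSV goes next to it with suffix
    ``.tsv``. ``reports`` maps image names to their metric bundles.
    """
    if not reports:
        raise ValueError("write_report requires at least one report")
    path = Path(path)
    payload = {
        "images": {name: asdict(r) for name, r in reports.items()},
        "macro": asdict(macro),
    }
    path.write_text(json.dumps(payload, indent=2))

    columns = ["pixel_error", "rand_error", "warping_error", "precision", "recall", "f_score"]
    lines = ["\t".join(["image"] + columns)]
    for name, r in reports.items():
        lines.append("\t".join([name] + [f"{getattr(r, c):.6f}" for c in columns]))
    macro_row = [
        "average",
        f"{1.0 - macro.macro_f_score:.6f}",
        f"{macro.macro_rand_error:.6f}",
        f"{macro.macro_warping_error:.6f}",
        f"{macro.macro_precision:.6f}",
        f"{macro.macro_recall:.6f}",
        f"{macro.macro_f_score:.6f}",
    ]
    # the macro pixel-error column is the mean of the per-image values
    macro_row[1] = f"{np.mean([r.pixel_error for r in reports.values()]):.6f}"
    lines.append("\t".join(macro_row))
    path.with_suffix(".tsv").write_text("\n".join(lines) + "\n")
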