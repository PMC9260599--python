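"""Slide tiling: cut a slide raster gaplessly into fixed-size patches.

A "slide" here is any 2-D RGB raster — a pyramid level exported from a
whole-slide scanner, or a plain PNG/TIFF/JPEG standing in for one.  Tiling
is a gapless, non-overlapping grid in row-major order; partial cells at the
right/bottom edge are emitted as-is (the QC size criterion rejects them
later, mirroring the pipeline order used on the clinical cohort).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Patch",
    "SlideRecord",
    "tile_slide",
    "read_slide_image",
    "read_manifest",
]

#: default tile edge, pixels
DEFAULT_PATCH_SIZE = 128


@dataclass
class Patch:
    """One rectangular tile cut from a slide.

    ``origin`` is the (x, y) pixel offset of the top-left corner in slide
    coordinates, 0-based, x = column, y = row.  ``label`` is the binary
    treatment-response label inherited from the parent slide (1 =
    effective/positive, 0 = ineffective/negative) or None when the slide
    is unlabeled.
    """

    slide_id: str
    origin: tuple[int, int]
    pixels: np.ndarray  # (h, w, 3) uint8
    label: Optional[int] = None

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])


@dataclass
class SlideRecord:
    """A slide with identity, provenance and (optionally) pixels.

    ``role`` distinguishes the feature-discovery set ("train") from the
    held-out validation set ("validation").  ``label`` is 1 for an
    effective treatment response, 0 for ineffective, None if not assigned.
    """

    slide_id: str
    patient_id: str
    path: Optional[str] = None
    role: str = "train"
    label: Optional[int] = None
    raster: Optional[np.ndarray] = field(default=None, repr=False)

    def load_raster(self, level: int = 0) -> np.ndarray:
        if self.raster is None:
            if self.path is None:
                raise ValueError(f"slide {self.slide_id!r} has neither raster nor path")
            self.raster = read_slide_image(self.path, level=level)
        return self.raster


def read_slide_image(path: str, level: int = 0) -> np.ndarray:
    """Read an RGB raster from a plain image or multi-page TIFF.

    For multi-page TIFFs each page is treated as one pyramid level
    (page 0 = highest resolution).  Plain PNG/JPEG images have a single
    level, 0.

    Raises
    ------
    IOError
        If the file does not exist or cannot be decoded.
    ValueError
        If ``level`` is not available; the message lists available levels.
    """
    if not os.path.exists(path):
        raise IOError(f"slide file not found: {path}")
    arr: np.ndarray
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        with tifffile.TiffFile(path) as tf:
            n_levels = len(tf.pages)
            if not 0 <= level < n_levels:
                raise ValueError(
                    f"pyramid level {level} not present in {path}; "
                    f"available levels: {list(range(n_levels))}"
                )
            arr = tf.pages[level].asarray()
    else:
        import imageio.v3 as iio

        if level != 0:
            raise ValueError(
                f"pyramid level {level} not present in {path}; available levels: [0]"
            )
        try:
            arr = iio.imread(path)
        except Exception as exc:  # pragma: no cover - backend-specific
            raise IOError(f"could not read slide image {path}: {exc}") from exc
    return _as_rgb_uint8(arr, path)


def _as_rgb_uint8(arr: np.ndarray, origin: str = "<array>") -> np.ndarray:
    if arr.ndim == 2:  # grayscale -> replicate
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{origin}: expected an RGB raster, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def tile_slide(
    slide: SlideRecord,
    patch_size: int = DEFAULT_PATCH_SIZE,
    level: int = 0,
) -> list[Patch]:
    """Cut a slide gaplessly into ``patch_size`` x ``patch_size`` patches.

    Every pixel of the raster is covered exactly once; partial cells at the
    right/bottom edges are returned with width/height < ``patch_size``.
    Patches are ordered row-major (top-to-bottom, left-to-right) and each
    origin is a multiple of ``patch_size`` on both axes.
    """
    if patch_size < 1:
        raise ValueError(f"patch_size must be >= 1, got {patch_size}")
    raster = slide.load_raster(level=level)
    raster = _as_rgb_uint8(raster, slide.slide_id)
    h, w = raster.shape[:2]
    patches: list[Patch] = []
    for y in range(0, h, patch_size):
        for x in range(0, w, patch_size):
            tile = raster[y : y + patch_size, x : x + patch_size]
            patches.append(
                Patch(
                    slide_id=slide.slide_id,
                    origin=(x, y),
                    pixels=np.ascontiguousarray(tile),
                    label=slide.label,
                )
            )
    return patches


_LABEL_ALIASES = {
    "1": 1, "effective": 1, "positive": 1, "pos": 1,
    "0": 0, "ineffective": 0, "negative": 0, "neg": 0,
    "": None, "na": None, "nan": None, "none": None,
}


def _parse_label(raw) -> Optional[int]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return None
    key = str(raw).strip().lower()
    if key not in _LABEL_ALIASES:
        raise ValueError(f"unrecognized response label {raw!r}")
    return _LABEL_ALIASES[key]


def read_manifest(path: str) -> list[SlideRecord]:
    """Read a slide manifest CSV/TSV.

    Required columns: slide_id, patient_id, path; optional: role, label.
    Labels accept 0/1 or effective/ineffective spellings.  slide_id must be
    unique.
    """
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    required = {"slide_id", "patient_id", "path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    if df["slide_id"].duplicated().any():
        dup = df.loc[df["slide_id"].duplicated(), "slide_id"].iloc[0]
        raise ValueError(f"duplicate slide_id in manifest: {dup!r}")
    base = os.path.dirname(os.path.abspath(path))
    records = []
    for row in df.itertuples(index=False):
        slide_path = row.path
        if slide_path and not os.path.isabs(slide_path):
            slide_path = os.path.join(base, slide_path)
        records.append(
            SlideRecord(
                slide_id=row.slide_id,
                patient_id=row.patient_id,
                path=slide_path,
                role=getattr(row, "role", "train") or "train",
                label=_parse_label(getattr(row, "label", None)),
            )
        )
    return records


def patches_to_array(patches: Sequence[Patch]) -> np.ndarray:
    """Stack same-shaped patches into an (n, h, w, 3) uint8 array."""
    if not patches:
        raise ValueError("empty patch sequence")
    shapes = {p.pixels.shape for p in patches}
    if len(shapes) != 1:
        raise ValueError(f"patches have non-uniform shapes: {sorted(shapes)}")
    return np.stack([p.pixels for p in patches])
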