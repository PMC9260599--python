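"""Patch quality control.

Four rejection criteria, applied first-cause in a fixed order:

  size        width or height < 128 px (partial tiles at the slide edge)
  blank       fraction of near-white pixels >= 0.75 (too little tissue)
  brightness  mean of all channel values < 120 or > 250 (too dark / bright)
  variance    population variance of all channel values < 80 (contamination,
              near-constant content)

"Blank" is defined as all three channels >= ``blank_threshold`` (default
240), the usual near-white background convention for H&E slides.
Brightness and variance are computed over the flattened 3*N channel values
on the 0-255 scale; variance uses ddof=0.  Size is checked first: edge
patches cannot be meaningfully scored, and the check is free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import numpy as np

from .tiling import Patch

__all__ = [
    "QCParams",
    "QCReport",
    "is_blank_pixel",
    "blank_fraction",
    "filter_patch",
    "filter_patchset",
]

#: rejection criteria in evaluation order (first failing one is reported)
CRITERIA = ("size", "blank", "brightness", "variance")


@dataclass(frozen=True)
class QCParams:
    """Thresholds of the four filter criteria; defaults match the study."""

    min_size: int = 128
    blank_threshold: int = 240          # per-channel near-white cutoff
    max_blank_fraction: float = 0.75
    min_brightness: float = 120.0
    max_brightness: float = 250.0
    min_variance: float = 80.0


@dataclass
class QCReport:
    """First-cause rejection counts for one filtering run."""

    n_input: int = 0
    n_rejected_by_criterion: dict = field(
        default_factory=lambda: {c: 0 for c in CRITERIA}
    )
    n_passed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def check(self) -> None:
        total = self.n_passed + sum(self.n_rejected_by_criterion.values())
        if total != self.n_input:
            raise AssertionError(
                f"inconsistent QC report: {total} accounted vs {self.n_input} input"
            )


def is_blank_pixel(pixel: Sequence[int], blank_threshold: int = 240) -> bool:
    """True iff all three channels are >= ``blank_threshold`` (near-white)."""
    r, g, b = pixel[0], pixel[1], pixel[2]
    return bool(r >= blank_threshold and g >= blank_threshold and b >= blank_threshold)


def blank_fraction(pixels: np.ndarray, blank_threshold: int = 240) -> float:
    """Fraction of pixels whose three channels are all >= the threshold."""
    mask = np.all(pixels >= blank_threshold, axis=-1)
    return float(mask.mean()) if mask.size else 0.0


def _validate_pixels(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError(f"expected an (h, w, 3) RGB patch, got shape {pixels.shape}")
    if pixels.dtype != np.uint8:
        raise ValueError(f"expected 8-bit channels, got dtype {pixels.dtype}")
    return pixels


def filter_patch(patch: Patch, params: QCParams = QCParams()) -> Optional[str]:
    """Return None if the patch passes QC, else the first failing criterion.

    Criteria are evaluated in the order size, blank, brightness, variance,
    and only the first failure is reported.
    """
    pixels = _validate_pixels(patch.pixels)
    if patch.width < params.min_size or patch.height < params.min_size:
        return "size"
    if blank_fraction(pixels, params.blank_threshold) >= params.max_blank_fraction:
        return "blank"
    values = pixels.reshape(-1).astype(np.float64)
    brightness = values.mean()
    if brightness < params.min_brightness or brightness > params.max_brightness:
        return "brightness"
    if values.var(ddof=0) < params.min_variance:
        return "variance"
    return None


def filter_patchset(
    patches: Iterable[Patch], params: QCParams = QCParams()
) -> tuple[list[Patch], QCReport]:
    """Filter a patch set, preserving input order among survivors."""
    report = QCReport()
    passed: list[Patch] = []
    for patch in patches:
        report.n_input += 1
        criterion = filter_patch(patch, params)
        if criterion is None:
            report.n_passed += 1
            passed.append(patch)
        else:
            report.n_rejected_by_criterion[criterion] += 1
    report.check()
    return passed, report
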