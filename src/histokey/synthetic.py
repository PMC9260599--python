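"""Labeled pseudo-slides with known texture-class composition.

Generates cohorts of synthetic "slides" assembled from 128-px cells of
procedural texture classes (blob-speckled, striped, speckled, ringed,
near-blank).  Each slide's per-class cell composition depends on its
binary response label, which is the single mechanism tying clusters to
outcome — so the impact score I of the cluster matching class c has the
closed-form expectation

    rho_c = p_c / (p_c + q_c)

where p_c / q_c are the class-c cell probabilities on positive / negative
slides (with equally many patches per label).  Textures are separable by
color and structure, not histologically realistic; they exist to give the
pipeline a recoverable ground truth.

All randomness flows from a single cohort seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tiling import Patch, SlideRecord, tile_slide

__all__ = [
    "TextureClassSpec",
    "PseudoSlideSpec",
    "Cohort",
    "DEFAULT_CLASSES",
    "DEFAULT_POS_COMPOSITION",
    "DEFAULT_NEG_COMPOSITION",
    "designed_rho",
    "make_patch",
    "make_slide",
    "make_cohort",
    "tile_cohort",
]

CELL = 128  # texture cell edge, matches the tiling patch size


@dataclass(frozen=True)
class TextureClassSpec:
    """One procedural texture class.

    ``kind`` selects the generator; ``base_color`` dominates the class's
    position in pixel/latent space; ``density``/``element_size`` shape the
    structure; ``noise_sd`` adds per-pixel Gaussian noise.  All non-blank
    kinds are tuned to pass the QC filter.
    """

    class_id: int
    kind: str  # blobs | stripes | speckle | rings | near_blank
    base_color: tuple[int, int, int]
    density: float = 1.0
    element_size: float = 4.0
    noise_sd: float = 12.0
    orientation: float = 0.0  # radians, stripes only


#: four QC-passing classes with distinct colors and structure; a cohort's
#: label-conditional compositions over them set the designed enrichments.
DEFAULT_CLASSES: tuple[TextureClassSpec, ...] = (
    TextureClassSpec(0, "blobs", (150, 110, 180), density=0.7, element_size=3.5),
    TextureClassSpec(1, "stripes", (235, 170, 150), element_size=6.0, orientation=0.6),
    TextureClassSpec(2, "speckle", (150, 200, 140), density=0.8),
    TextureClassSpec(3, "rings", (120, 150, 215), density=0.8, element_size=8.0),
)

#: class probabilities per cell, conditional on the slide label
DEFAULT_POS_COMPOSITION = (0.40, 0.30, 0.20, 0.10)
DEFAULT_NEG_COMPOSITION = (0.10, 0.20, 0.30, 0.40)


def designed_rho(
    pos_composition: Sequence[float], neg_composition: Sequence[float]
) -> np.ndarray:
    """Expected impact score per class: p / (p + q), equal label totals."""
    p = np.asarray(pos_composition, dtype=float)
    q = np.asarray(neg_composition, dtype=float)
    return p / (p + q)


def make_patch(spec: TextureClassSpec, seed: int, size: int = CELL) -> Patch:
    """Render one texture cell as a Patch (deterministic per seed)."""
    rng = np.random.default_rng(seed)
    img = np.ones((size, size, 3), dtype=np.float64) * np.array(spec.base_color, float)
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)

    if spec.kind == "blobs":
        n = max(1, int(spec.density * 40))
        for _ in range(n):
            cy, cx = rng.uniform(0, size, size=2)
            r = spec.element_size * rng.uniform(0.6, 1.4)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 < r * r
            img[mask] *= 0.45
    elif spec.kind == "stripes":
        theta = spec.orientation + rng.uniform(-0.2, 0.2)
        phase = rng.uniform(0, 2 * np.pi)
        coord = xx * np.cos(theta) + yy * np.sin(theta)
        wave = np.sin(2 * np.pi * coord / (2 * spec.element_size) + phase)
        img *= (0.85 + 0.15 * wave)[:, :, None]
    elif spec.kind == "speckle":
        mask = rng.random((size, size)) < 0.05 * spec.density
        img[mask] *= 0.5
    elif spec.kind == "rings":
        n = max(1, int(spec.density * 6))
        for _ in range(n):
            cy, cx = rng.uniform(0, size, size=2)
            r = spec.element_size * rng.uniform(1.5, 3.0)
            d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
            img[np.abs(d - r) < 2.0] *= 0.55
    elif spec.kind == "near_blank":
        img[:] = 250.0
        strip = max(1, int(size * 0.15))  # ~85% stays near-white
        img[:strip] = np.array(spec.base_color, float)
    else:
        raise ValueError(f"unknown texture kind {spec.kind!r}")

    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return Patch(slide_id=f"class{spec.class_id}", origin=(0, 0), pixels=pixels)


@dataclass
class PseudoSlideSpec:
    """Recipe for one synthetic slide."""

    slide_id: str
    patient_id: str
    label: int  # 1 effective, 0 ineffective
    grid: tuple[int, int] = (6, 6)  # rows, cols of 128-px cells
    composition: Sequence[float] = DEFAULT_POS_COMPOSITION
    seed: int = 0


def make_slide(
    spec: PseudoSlideSpec, classes: Sequence[TextureClassSpec] = DEFAULT_CLASSES
) -> tuple[SlideRecord, np.ndarray]:
    """Assemble a slide raster from label-conditional texture cells.

    Returns the SlideRecord (raster in memory) and the (rows, cols)
    ground-truth map of cell class ids.
    """
    rows, cols = spec.grid
    if rows < 2 or cols < 2:
        raise ValueError(f"grid must be at least 2x2, got {spec.grid}")
    comp = np.asarray(spec.composition, dtype=float)
    if len(comp) != len(classes):
        raise ValueError("composition length must match number of classes")
    if not np.isclose(comp.sum(), 1.0):
        raise ValueError(f"composition must sum to 1, got {comp.sum()}")
    rng = np.random.default_rng(spec.seed)
    cell_map = rng.choice(len(classes), size=(rows, cols), p=comp)
    raster = np.empty((rows * CELL, cols * CELL, 3), dtype=np.uint8)
    for r in range(rows):
        for c in range(cols):
            cell_seed = int(rng.integers(0, 2**31))
            patch = make_patch(classes[cell_map[r, c]], seed=cell_seed)
            raster[r * CELL : (r + 1) * CELL, c * CELL : (c + 1) * CELL] = patch.pixels
    record = SlideRecord(
        slide_id=spec.slide_id,
        patient_id=spec.patient_id,
        role="train",
        label=spec.label,
        raster=raster,
    )
    return record, cell_map


@dataclass
class Cohort:
    """A complete synthetic study input set with ground truth."""

    slides: list[SlideRecord]
    cell_maps: dict[str, np.ndarray]
    classes: Sequence[TextureClassSpec]
    pos_composition: Sequence[float]
    neg_composition: Sequence[float]
    seed: int = 0

    @property
    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "slide_id": [s.slide_id for s in self.slides],
                "patient_id": [s.patient_id for s in self.slides],
                "path": [f"slides/{s.slide_id}.png" for s in self.slides],
                "role": [s.role for s in self.slides],
                "label": [s.label for s in self.slides],
            }
        )

    @property
    def labels(self) -> dict[str, int]:
        return {s.slide_id: s.label for s in self.slides}

    @property
    def designed_rho(self) -> np.ndarray:
        return designed_rho(self.pos_composition, self.neg_composition)


def make_cohort(
    n_slides: int = 20,
    classes: Sequence[TextureClassSpec] = DEFAULT_CLASSES,
    pos_composition: Sequence[float] = DEFAULT_POS_COMPOSITION,
    neg_composition: Sequence[float] = DEFAULT_NEG_COMPOSITION,
    grid: tuple[int, int] = (6, 6),
    label_balance: float = 0.5,
    seed: int = 0,
    out_dir: Optional[str] = None,
) -> Cohort:
    """Generate a labeled cohort of pseudo-slides (optionally written to disk).

    Labels alternate to the requested balance; one patient per slide.  When
    ``out_dir`` is given, writes slides/*.png, manifest.csv and truth.json —
    a complete runnable input set.
    """
    if n_slides < 4:
        raise ValueError(f"need at least 4 slides, got {n_slides}")
    n_pos = int(round(n_slides * label_balance))
    labels = [1] * n_pos + [0] * (n_slides - n_pos)
    master = np.random.default_rng(seed)
    slides, cell_maps = [], {}
    for i, label in enumerate(labels):
        spec = PseudoSlideSpec(
            slide_id=f"S{i:03d}",
            patient_id=f"P{i:03d}",
            label=label,
            grid=grid,
            composition=pos_composition if label == 1 else neg_composition,
            seed=int(master.integers(0, 2**31)),
        )
        record, cell_map = make_slide(spec, classes)
        slides.append(record)
        cell_maps[record.slide_id] = cell_map
    cohort = Cohort(
        slides=slides,
        cell_maps=cell_maps,
        classes=classes,
        pos_composition=tuple(pos_composition),
        neg_composition=tuple(neg_composition),
        seed=seed,
    )
    if out_dir is not None:
        _write_cohort(cohort, out_dir)
    return cohort


def _write_cohort(cohort: Cohort, out_dir: str) -> None:
    import imageio.v3 as iio

    os.makedirs(os.path.join(out_dir, "slides"), exist_ok=True)
    for slide in cohort.slides:
        iio.imwrite(os.path.join(out_dir, "slides", f"{slide.slide_id}.png"), slide.raster)
    cohort.manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    truth = {
        "seed": cohort.seed,
        "pos_composition": list(cohort.pos_composition),
        "neg_composition": list(cohort.neg_composition),
        "designed_rho": [float(v) for v in cohort.designed_rho],
        "classes": [asdict(c) for c in cohort.classes],
        "cell_maps": {sid: m.tolist() for sid, m in cohort.cell_maps.items()},
    }
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1)


def tile_cohort(
    cohort: Cohort, patch_size: int = CELL
) -> tuple[list[Patch], np.ndarray]:
    """Tile every slide; return patches plus aligned ground-truth class ids.

    With ``patch_size`` equal to the cell size, the row-major tiling of each
    slide lines up exactly with its cell map.
    """
    patches: list[Patch] = []
    truth: list[int] = []
    for slide in cohort.slides:
        cell_map = cohort.cell_maps[slide.slide_id]
        for patch in tile_slide(slide, patch_size=patch_size):
            x, y = patch.origin
            patches.append(patch)
            truth.append(int(cell_map[y // CELL, x // CELL]))
    return patches, np.asarray(truth)
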