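"""End-to-end convenience: tile -> QC -> encode -> cluster -> score -> predict.

Thin orchestration over the per-stage modules, used by the CLI and by the
parameter-recovery experiments on synthetic cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .autoencoder import PatchAutoencoder
from .prediction import CVResult, build_slide_vectors, crossvalidate
from .qc import QCParams, QCReport, filter_patchset
from .scoring import ImpactFeatureModel
from .tiling import Patch, SlideRecord, tile_slide

__all__ = ["DiscoveryResult", "collect_patches", "discover_features"]


@dataclass
class DiscoveryResult:
    """Everything the feature-discovery pass produces."""

    autoencoder: PatchAutoencoder
    features: ImpactFeatureModel
    patches: list[Patch]
    latents: np.ndarray
    clusters: np.ndarray
    qc_report: QCReport
    slide_vectors: pd.DataFrame
    slide_labels: pd.Series

    def crossvalidate(self, family: str = "logistic", n_folds: int = 10,
                      seed: Optional[int] = None) -> CVResult:
        return crossvalidate(
            self.slide_vectors.values, self.slide_labels.values,
            family=family, n_folds=n_folds, seed=seed,
        )


def collect_patches(
    slides: Sequence[SlideRecord],
    patch_size: int = 128,
    qc_params: QCParams = QCParams(),
) -> tuple[list[Patch], QCReport]:
    """Tile every slide and apply QC; survivors keep slide order."""
    all_patches: list[Patch] = []
    for slide in slides:
        all_patches.extend(tile_slide(slide, patch_size=patch_size))
    return filter_patchset(all_patches, qc_params)


def discover_features(
    slides: Sequence[SlideRecord],
    latent_dim: int = 2048,
    epochs: int = 50,
    n_clusters: Optional[int] = None,
    batch_size: int = 64,
    seed: Optional[int] = None,
    patch_size: int = 128,
    qc_params: QCParams = QCParams(),
    morphology=None,
) -> DiscoveryResult:
    """Run the full unsupervised discovery pass on labeled slides.

    ``n_clusters`` defaults to the number of distinct slides, matching the
    reference workflow.  The single ``seed`` drives autoencoder training
    and k-means.
    """
    patches, report = collect_patches(slides, patch_size=patch_size, qc_params=qc_params)
    if not patches:
        raise ValueError("no patches survived quality control")
    labels = np.array([p.label for p in patches])
    if any(l is None for l in labels):
        raise ValueError("all slides must carry a response label")
    slide_ids = np.array([p.slide_id for p in patches])

    ae = PatchAutoencoder(
        latent_dim=latent_dim, epochs=epochs, batch_size=batch_size, random_state=seed
    ).fit(patches)
    latents = ae.transform(patches)

    fm = ImpactFeatureModel(
        n_clusters=n_clusters, random_state=seed
    ).fit(latents, labels.astype(int), slide_ids=slide_ids, morphology=morphology)

    vectors = build_slide_vectors(fm.labels_, slide_ids, fm.feature_model_)
    slide_label = (
        pd.DataFrame({"slide_id": slide_ids, "label": labels.astype(int)})
        .groupby("slide_id", sort=False)["label"].first()
        .reindex(vectors.index)
    )
    return DiscoveryResult(
        autoencoder=ae,
        features=fm,
        patches=patches,
        latents=latents,
        clusters=fm.labels_,
        qc_report=report,
        slide_vectors=vectors,
        slide_labels=slide_label,
    )
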