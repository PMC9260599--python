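"""Cluster impact scores, weights, polarity and key-feature selection.

Each patch inherits the binary treatment-response label of its slide
(positive = effective, negative = ineffective).  For cluster k, with
n+ / n- the total numbers of positive / negative patches over all
clustered patches:

    r+_k = (positive patches in k) / n+
    r-_k = (negative patches in k) / n-
    I_k  = r+_k / (r+_k + r-_k)          impact score, in [0, 1]
    W_k  = 1 + |0.5 - I_k|               weight, in [1, 1.5]

I_k > 0.5 marks a cluster enriched in patches from responders (positive
feature), I_k < 0.5 a cluster enriched in non-responders (negative), and
I_k = 0.5 is neutral.  A cluster is a *key feature* when W_k exceeds a
threshold (default 1.1) and its morphology is tissue-driven ("histology")
rather than a tile-geometry artifact ("shape").  Morphology normally comes
from an expert annotation file; a blank-fraction heuristic stands in when
none is supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from importlib import resources
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .clustering import CentroidSet, fit_kmeans, assign_latents
from .qc import blank_fraction
from .tiling import Patch

__all__ = [
    "FeatureScore",
    "FeatureModel",
    "ImpactFeatureModel",
    "impact_score",
    "weight_from_impact",
    "polarity_of",
    "label_patches",
    "compute_scores",
    "select_key_features",
    "classify_shape_heuristic",
    "scores_to_frame",
    "load_reference_clusters",
]

logger = logging.getLogger(__name__)

DEFAULT_KEY_THRESHOLD = 1.1
SHAPE_BLANK_FRACTION = 0.35


def impact_score(r_plus: float, r_minus: float) -> float:
    """I = r+ / (r+ + r-); defined as the neutral 0.5 for an empty cluster."""
    denom = r_plus + r_minus
    if denom == 0.0:
        return 0.5
    return r_plus / denom


def weight_from_impact(impact) -> np.ndarray | float:
    """W = 1 + |0.5 - I|, the distance from outcome-neutrality plus one."""
    return 1.0 + np.abs(0.5 - np.asarray(impact, dtype=float))


def polarity_of(impact: float) -> str:
    if impact > 0.5:
        return "positive"
    if impact < 0.5:
        return "negative"
    return "neutral"


@dataclass
class FeatureScore:
    """Per-cluster association with treatment response."""

    cluster_id: int
    size: int
    n_pos: int
    n_neg: int
    r_plus: float
    r_minus: float
    impact: float          # I_k
    weight: float          # W_k
    polarity: str          # positive | negative | neutral
    morphology: str = "unknown"   # shape | histology | unknown
    is_key: bool = False
    empty: bool = False


@dataclass
class FeatureModel:
    """Centroids plus scored clusters: the fitted feature dictionary."""

    centroids: Optional[CentroidSet]
    scores: list[FeatureScore]
    key_threshold: float = DEFAULT_KEY_THRESHOLD

    @property
    def k(self) -> int:
        return len(self.scores)

    @property
    def weights(self) -> np.ndarray:
        return np.array([s.weight for s in self.scores])

    @property
    def key_clusters(self) -> list[int]:
        return [s.cluster_id for s in self.scores if s.is_key]

    def frame(self) -> pd.DataFrame:
        return scores_to_frame(self.scores)


def label_patches(
    assignments: pd.DataFrame, manifest: Mapping[str, Optional[int]]
) -> pd.DataFrame:
    """Attach each patch's parent-slide response label to its assignment row.

    ``assignments`` needs a ``slide_id`` column; ``manifest`` maps slide_id
    to a binary label.  Raises if any slide is absent or unlabeled.
    """
    labels = []
    for sid in assignments["slide_id"]:
        if sid not in manifest:
            raise ValueError(f"slide {sid!r} missing from manifest")
        lab = manifest[sid]
        if lab is None:
            raise ValueError(f"slide {sid!r} has no response label")
        labels.append(int(lab))
    out = assignments.copy()
    out["label"] = labels
    return out


def compute_scores(
    clusters: Sequence[int],
    labels: Sequence[int],
    k: Optional[int] = None,
    cluster_ids: Optional[Sequence[int]] = None,
) -> list[FeatureScore]:
    """Score every cluster from labeled patch assignments.

    ``clusters[i]`` is the 0-based cluster index of patch i, ``labels[i]``
    its binary response label.  ``cluster_ids`` optionally renames the
    clusters in the output (e.g. 1-based ids); defaults to 0..k-1.
    """
    clusters = np.asarray(clusters, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if clusters.shape != labels.shape:
        raise ValueError("clusters and labels must have equal length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n_plus = int((labels == 1).sum())
    n_minus = int((labels == 0).sum())
    if n_plus == 0 or n_minus == 0:
        raise ValueError(
            "both labels must be present among clustered patches "
            f"(n+={n_plus}, n-={n_minus})"
        )
    if k is None:
        k = int(clusters.max()) + 1 if len(clusters) else 0
    if cluster_ids is None:
        cluster_ids = list(range(k))
    if len(cluster_ids) != k:
        raise ValueError("cluster_ids length must equal k")

    scores = []
    for idx in range(k):
        member = clusters == idx
        n_pos = int((member & (labels == 1)).sum())
        n_neg = int((member & (labels == 0)).sum())
        r_plus = n_pos / n_plus
        r_minus = n_neg / n_minus
        empty = (n_pos + n_neg) == 0
        impact = impact_score(r_plus, r_minus)
        scores.append(
            FeatureScore(
                cluster_id=int(cluster_ids[idx]),
                size=n_pos + n_neg,
                n_pos=n_pos,
                n_neg=n_neg,
                r_plus=r_plus,
                r_minus=r_minus,
                impact=impact,
                weight=float(weight_from_impact(impact)),
                polarity=polarity_of(impact),
                empty=empty,
            )
        )
    return scores


def classify_shape_heuristic(
    members: Sequence[Patch], blank_fraction_threshold: float = SHAPE_BLANK_FRACTION
) -> str:
    """Fallback morphology call: high mean blank fraction -> "shape".

    Tile-geometry clusters group by blank margins rather than tissue; when
    no expert annotation is available, a cluster whose members average more
    than ``blank_fraction_threshold`` near-white pixels is called "shape".
    """
    fractions = [blank_fraction(p.pixels) for p in members if p.pixels is not None]
    if not fractions:
        logger.warning("no member pixels available; defaulting morphology to histology")
        return "histology"
    return "shape" if float(np.mean(fractions)) > blank_fraction_threshold else "histology"


def select_key_features(
    scores: Sequence[FeatureScore],
    key_threshold: float = DEFAULT_KEY_THRESHOLD,
    morphology: Optional[Mapping[int, str]] = None,
    centroids: Optional[CentroidSet] = None,
    members_by_cluster: Optional[Mapping[int, Sequence[Patch]]] = None,
) -> FeatureModel:
    """Flag key features: W_k > threshold and morphology is not "shape".

    ``morphology`` maps cluster_id to "shape"/"histology" (an expert
    annotation table); if absent, the blank-fraction heuristic runs on
    ``members_by_cluster`` where provided, else morphology stays unknown
    and is treated as histology for key selection.
    """
    known = {s.cluster_id for s in scores}
    if morphology is not None:
        unknown = set(morphology) - known
        if unknown:
            raise ValueError(f"morphology annotations for unknown clusters: {sorted(unknown)}")
    out = []
    for s in scores:
        morph = s.morphology
        if morphology is not None and s.cluster_id in morphology:
            morph = morphology[s.cluster_id]
            if morph not in ("shape", "histology"):
                raise ValueError(f"invalid morphology {morph!r} for cluster {s.cluster_id}")
        elif members_by_cluster is not None and s.cluster_id in members_by_cluster:
            morph = classify_shape_heuristic(members_by_cluster[s.cluster_id])
        is_key = s.weight > key_threshold and morph != "shape"
        out.append(
            FeatureScore(**{**asdict(s), "morphology": morph, "is_key": is_key})
        )
    return FeatureModel(centroids=centroids, scores=out, key_threshold=key_threshold)


def scores_to_frame(scores: Sequence[FeatureScore]) -> pd.DataFrame:
    """Scores as a table directly comparable to the published cluster table."""
    df = pd.DataFrame([asdict(s) for s in scores])
    return df.rename(
        columns={"cluster_id": "cluster", "impact": "I_k", "weight": "W_k"}
    )


def load_reference_clusters() -> pd.DataFrame:
    """Published 38-cluster reference table (oral lichen planus cohort).

    Columns: cluster (1-based id), impact_score (I_k), n_patches, and the
    expert morphology description; rows whose morphology reads "shape" are
    tile-geometry clusters.  Used as a worked example and regression
    fixture.
    """
    with resources.files("histokey.data").joinpath("olp_reference_clusters.csv").open() as fh:
        df = pd.read_csv(fh)
    df["morphology_class"] = np.where(
        df["morphology"].str.strip().str.lower() == "shape", "shape", "histology"
    )
    return df


class ImpactFeatureModel(BaseEstimator):
    """Cluster latent vectors into features and score each against outcome.

    Fit on per-patch latent vectors with binary patch labels (inherited
    from slides); learns k-means centroids, per-cluster impact scores I_k
    and weights W_k, and the key-feature flags.  ``transform`` turns patch
    latents grouped by slide into W-weighted slide occupancy vectors for
    downstream classifiers.

    Parameters
    ----------
    n_clusters : int or None
        Number of features; None means "number of distinct slides seen in
        fit" (requires slide_ids), matching the reference workflow.
    key_threshold : float, default 1.1
        W_k cutoff for key features.
    random_state : int or None
        K-means seed.
    """

    def __init__(
        self,
        n_clusters: Optional[int] = None,
        key_threshold: float = DEFAULT_KEY_THRESHOLD,
        random_state: Optional[int] = None,
    ):
        self.n_clusters = n_clusters
        self.key_threshold = key_threshold
        self.random_state = random_state

    def fit(self, X, y, slide_ids=None, morphology=None, members_by_cluster=None):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        k = self.n_clusters
        if k is None:
            if slide_ids is None:
                raise ValueError("n_clusters=None requires slide_ids to infer k")
            k = len(pd.unique(np.asarray(slide_ids)))
        self.centroids_ = fit_kmeans(X, k, seed=self.random_state)
        labels, _ = assign_latents(X, self.centroids_)
        self.labels_ = labels
        scores = compute_scores(labels, y, k=k)
        model = select_key_features(
            scores,
            key_threshold=self.key_threshold,
            morphology=morphology,
            centroids=self.centroids_,
            members_by_cluster=members_by_cluster,
        )
        self.feature_model_ = model
        self.scores_ = model.frame()
        self.weights_ = model.weights
        self.key_clusters_ = model.key_clusters
        return self

    def assign(self, X) -> np.ndarray:
        """Nearest-centroid cluster index for each latent vector."""
        labels, _ = assign_latents(np.asarray(X, dtype=np.float64), self.centroids_)
        return labels

    def transform(self, X, slide_ids) -> pd.DataFrame:
        """W-weighted per-slide cluster-occupancy vectors.

        Returns a DataFrame indexed by slide_id (first-appearance order)
        with k columns; entry (s, k) is the fraction of slide s's patches
        in cluster k times W_k.
        """
        from .prediction import build_slide_vectors

        labels = self.assign(X)
        return build_slide_vectors(labels, slide_ids, self.feature_model_)
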