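"""Overlay rendering and run reports.

``render_overlay`` draws a colored border around each QC-passed patch on
the slide raster — red for patches in positive clusters, blue for
negative, gray for neutral — leaving all non-border pixels untouched.
``render_report`` aggregates already-computed artifacts (scores table,
cross-validation metrics) into a Markdown report with figures; it never
recomputes numbers.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import FeatureModel

__all__ = ["OverlayStyle", "render_overlay", "render_report"]


@dataclass(frozen=True)
class OverlayStyle:
    positive_color: tuple[int, int, int] = (255, 0, 0)   # red
    negative_color: tuple[int, int, int] = (0, 0, 255)   # blue
    neutral_color: tuple[int, int, int] = (128, 128, 128)
    border_width: int = 3

    def __post_init__(self):
        colors = {self.positive_color, self.negative_color, self.neutral_color}
        if len(colors) != 3:
            raise ValueError("overlay colors must be pairwise distinct")


def render_overlay(
    raster: np.ndarray,
    assignments: pd.DataFrame,
    feature_model: FeatureModel,
    style: OverlayStyle = OverlayStyle(),
    sidecar_path: Optional[str] = None,
) -> np.ndarray:
    """Outline each assigned patch in its cluster's polarity color.

    ``assignments`` needs columns x, y, width, height, cluster (cluster as
    0-based index into the feature model's scores).  Returns a copy of the
    raster; the input is never modified.  An optional JSON sidecar keyed by
    "x,y" records each patch's cluster and W_k.
    """
    out = np.array(raster, copy=True)
    h, w = out.shape[:2]
    polarity = {i: s.polarity for i, s in enumerate(feature_model.scores)}
    weights = {i: s.weight for i, s in enumerate(feature_model.scores)}
    color_of = {
        "positive": style.positive_color,
        "negative": style.negative_color,
        "neutral": style.neutral_color,
    }
    sidecar = {}
    bw = style.border_width
    for row in assignments.itertuples(index=False):
        x, y, pw, ph = int(row.x), int(row.y), int(row.width), int(row.height)
        if x < 0 or y < 0 or x + pw > w or y + ph > h:
            raise ValueError(f"assignment at ({x}, {y}) size {pw}x{ph} outside raster {w}x{h}")
        cluster = int(row.cluster)
        color = np.array(color_of[polarity[cluster]], dtype=out.dtype)
        out[y : y + ph, x : x + bw] = color
        out[y : y + ph, x + pw - bw : x + pw] = color
        out[y : y + bw, x : x + pw] = color
        out[y + ph - bw : y + ph, x : x + pw] = color
        sidecar[f"{x},{y}"] = {"cluster": cluster, "W_k": float(weights[cluster])}
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return out


def render_report(
    feature_model: FeatureModel,
    cv_results: Sequence[Mapping] = (),
    holdout: Optional[Mapping] = None,
    out_dir: str = ".",
    roc_curves: Optional[Mapping[str, tuple]] = None,
) -> str:
    """Write report.md (+ W_k bar chart and ROC figure) into ``out_dir``.

    ``cv_results`` are CVResult.to_dict() mappings; ``roc_curves`` maps a
    model-family name to (fpr, tpr) arrays.  Returns the report path.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    frame = feature_model.frame()

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.bar(frame["cluster"].astype(str), frame["W_k"], color="steelblue")
    ax.axhline(feature_model.key_threshold, color="firebrick", ls="--", lw=1,
               label=f"key threshold {feature_model.key_threshold}")
    ax.set_xlabel("feature (cluster)")
    ax.set_ylabel("$W_k$")
    ax.set_ylim(1.0, 1.5)
    ax.legend()
    fig.tight_layout()
    fig.savefig(os.path.join(out_dir, "weights.png"), dpi=120)
    plt.close(fig)

    if roc_curves:
        fig, ax = plt.subplots(figsize=(4, 4))
        for name, (fpr, tpr) in roc_curves.items():
            ax.plot(fpr, tpr, label=name)
        ax.plot([0, 1], [0, 1], "k:", lw=0.8)
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend()
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, "roc.png"), dpi=120)
        plt.close(fig)

    lines = ["# Feature discovery report", "", "## Cluster scores", ""]
    lines.append(frame.to_markdown(index=False))
    lines += ["", f"Key features (W_k > {feature_model.key_threshold}, "
              f"morphology != shape): {feature_model.key_clusters}", "",
              "![weights](weights.png)", ""]
    for res in cv_results:
        lines += [
            f"## Cross-validation — {res['family']}",
            "",
            f"- mean accuracy: {res['mean_accuracy']:.4f} "
            f"(min {res['min_accuracy']:.4f}, max {res['max_accuracy']:.4f})",
            f"- pooled AUC: {res['auc']:.4f}",
            f"- fold-mean AUC CI: [{res['auc_ci'][0]:.4f}, {res['auc_ci'][1]:.4f}]",
            "",
        ]
    if holdout is not None:
        lines += ["## Holdout", "",
                  f"- accuracy: {holdout['accuracy']:.4f}",
                  f"- AUC: {holdout['auc']:.4f}", ""]
    if roc_curves:
        lines += ["![roc](roc.png)", ""]
    path = os.path.join(out_dir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path
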