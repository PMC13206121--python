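"""Attention-map rasterization and polarity-agnostic alignment metrics.

NAAR (normalized attention alignment ratio) is the mean attention inside an
annotated region divided by the mean over all valid tissue; values near 1
are indistinguishable from a spatially random allocation, and |NAAR - 1|
measures departure from randomness regardless of whether the annotation
marks malignant or normal tissue (annotation sets routinely mix both
polarities). AMR (attention mass ratio) at threshold q is the fraction of
the top ceil(qN) attention patches lying inside the annotation; its random
baseline is the annotated area fraction. Both metrics work on raw per-patch
scores — NAAR's ratio form is invariant to positive rescaling, so display
normalization of heatmaps never affects them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import cohens_d_paired, wilcoxon_exact

__all__ = [
    "AlignmentRecord",
    "rasterize_attention",
    "save_heatmap",
    "naar",
    "amr",
    "alignment_record",
    "compare_features",
]

AMR_THRESHOLDS = (0.10, 0.25, 0.50)


def rasterize_attention(
    coords: np.ndarray, scores: np.ndarray, shape: Optional[tuple[int, int]] = None
) -> np.ndarray:
    """Patch-grid raster of attention scores; cells without tissue are NaN.

    ``coords`` are (col, row) grid positions; duplicates are an error.
    """
    coords = np.asarray(coords, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if coords.shape[0] != scores.shape[0]:
        raise ValueError("coords and scores length mismatch")
    keys = {tuple(c) for c in coords.tolist()}
    if len(keys) != len(coords):
        raise ValueError("duplicate patch coordinates")
    if shape is None:
        shape = (int(coords[:, 1].max()) + 1, int(coords[:, 0].max()) + 1)
    raster = np.full(shape, np.nan)
    raster[coords[:, 1], coords[:, 0]] = scores
    return raster


def save_heatmap(raster: np.ndarray, path) -> None:
    """Render a raster as a PNG heatmap (min-max scaled, display only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    finite = raster[np.isfinite(raster)]
    vmin = finite.min() if finite.size else 0.0
    vmax = finite.max() if finite.size else 1.0
    ax.imshow(raster, cmap="jet", vmin=vmin, vmax=vmax if vmax > vmin else vmin + 1)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)


def naar(scores: np.ndarray, annotation: np.ndarray) -> float:
    """Mean attention inside the annotation over mean attention everywhere.

    Uniform scores give exactly 1.0. Raises on an empty annotation or zero
    total attention (the ratio is then undefined).
    """
    scores = np.asarray(scores, dtype=float)
    annotation = np.asarray(annotation).astype(bool)
    if scores.shape != annotation.shape:
        raise ValueError("scores and annotation length mismatch")
    if not annotation.any():
        raise ValueError("empty annotation")
    mean_all = scores.mean()
    if mean_all == 0.0:
        raise ValueError("zero total attention; NAAR undefined")
    return float(scores[annotation].mean() / mean_all)


def amr(scores: np.ndarray, annotation: np.ndarray, q: float) -> float:
    """Fraction of the top-ceil(qN) attention patches inside the annotation.

    Ties in score are broken by ascending patch index, making the selected
    set deterministic.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    annotation = np.asarray(annotation).astype(bool)
    n = scores.size
    if n == 0:
        raise ValueError("empty tissue")
    k = int(np.ceil(q * n))
    order = np.lexsort((np.arange(n), -scores))
    return float(annotation[order[:k]].mean())


@dataclass
class AlignmentRecord:
    """Per-slide spatial alignment summary for one feature condition."""

    slide_id: str
    naar: float
    naar_dev: float  # |NAAR - 1|
    amr: dict[float, float]  # q -> AMR_q
    amr_dev: dict[float, float]  # q -> |AMR_q - annotated fraction|
    annotated_fraction: float
    polarity: str = "tumor"


def alignment_record(
    slide_id: str,
    scores: np.ndarray,
    annotation: np.ndarray,
    polarity: str = "tumor",
    thresholds: Sequence[float] = AMR_THRESHOLDS,
) -> AlignmentRecord:
    annotation = np.asarray(annotation).astype(bool)
    base = float(annotation.mean())
    value = naar(scores, annotation)
    amrs = {q: amr(scores, annotation, q) for q in thresholds}
    return AlignmentRecord(
        slide_id=slide_id, naar=value, naar_dev=abs(value - 1.0), amr=amrs,
        amr_dev={q: abs(v - base) for q, v in amrs.items()},
        annotated_fraction=base, polarity=polarity,
    )


def compare_features(
    records: dict[str, Sequence[AlignmentRecord]],
    alternative: str = "two-sided",
) -> dict:
    """Cross-feature comparison of attention alignment.

    ``records`` maps a feature-condition name to its per-slide alignment
    records. The comparison is restricted to slides evaluable under every
    condition; paired Wilcoxon signed-rank tests run on |NAAR - 1| per
    feature pair. Returns a per-feature summary table and a pairwise table.
    """
    if len(records) < 2:
        raise ValueError("need at least two feature conditions")
    by_feature = {
        feat: {r.slide_id: r for r in recs} for feat, recs in records.items()
    }
    common = set.intersection(*(set(d) for d in by_feature.values()))
    if not common:
        raise ValueError("no slide is evaluable under all feature conditions")
    common = sorted(common)

    summary_rows = []
    for feat, d in by_feature.items():
        naars = np.array([d[s].naar for s in common])
        devs = np.array([d[s].naar_dev for s in common])
        row = {
            "feature": feat, "n_slides": len(common),
            "naar_mean": naars.mean(), "naar_sd": naars.std(ddof=1),
            "naar_dev_mean": devs.mean(), "naar_dev_median": float(np.median(devs)),
        }
        for q in AMR_THRESHOLDS:
            row[f"amr_dev_q{int(q * 100)}"] = float(
                np.mean([d[s].amr_dev[q] for s in common])
            )
        summary_rows.append(row)

    feats = list(by_feature)
    pair_rows = []
    for i in range(len(feats)):
        for j in range(i + 1, len(feats)):
            a, b = feats[i], feats[j]
            da = np.array([by_feature[a][s].naar_dev for s in common])
            db = np.array([by_feature[b][s].naar_dev for s in common])
            try:
                res = wilcoxon_exact(da, db, alternative=alternative)
                p, stat = res.pvalue, res.statistic
            except ValueError:  # all differences zero
                p, stat = np.nan, np.nan
            eff = cohens_d_paired(da, db)
            pair_rows.append(
                {"comparison": f"{a} vs. {b}",
                 "delta_naar_dev": float((da - db).mean()),
                 "wilcoxon_w": stat, "p_value": p, "cohens_d": eff.d}
            )
    return {"summary": pd.DataFrame(summary_rows), "pairwise": pd.DataFrame(pair_rows)}
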