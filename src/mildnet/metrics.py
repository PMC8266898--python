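"""Segmentation loss and evaluation metrics: BCE-with-logits, Dice, IoU, Hausdorff.

Dice and IoU are the usual set-overlap measures over foreground pixels,

    DC  = 2 |Y ∩ Ŷ| / (|Y| + |Ŷ|),     IoU = |Y ∩ Ŷ| / |Y ∪ Ŷ|,

related by DC = 2·IoU / (1 + IoU). The Hausdorff distance is the
symmetric max of the two directed distances between the foreground
coordinate sets under the Euclidean metric, taken over ALL foreground
pixels (no boundary restriction). Conventions for degenerate inputs:
two empty masks are perfectly similar (DC = IoU = 1, HD = 0); one empty
mask against a non-empty one scores DC = IoU = 0 and HD equal to the
image diagonal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import directed_hausdorff


class ValidationError(ValueError):
    pass


def _as_binary_mask(mask, name: str = "mask") -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValidationError(f"{name} must be a rank-2 array, got rank {m.ndim}")
    if not np.isin(m, (0, 1)).all():
        raise ValidationError(f"{name} must be strictly binary (0/1)")
    return m.astype(bool)


def _check_same_shape(y: np.ndarray, yhat: np.ndarray) -> None:
    if y.shape != yhat.shape:
        raise ValidationError(f"mask shapes differ: {y.shape} vs {yhat.shape}")


def bce_with_logits(logits, targets) -> float:
    """Mean binary cross-entropy from raw logits (log-sum-exp form)."""
    z = np.asarray(logits, dtype=float)
    y = np.asarray(targets, dtype=float)
    if z.shape != y.shape:
        raise ValidationError(f"shape mismatch: logits {z.shape} vs targets {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValidationError("targets must be strictly binary (0/1)")
    loss = np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z)))
    return float(loss.mean())


def dice_coefficient(y, yhat) -> float:
    y = _as_binary_mask(y, "y")
    yh = _as_binary_mask(yhat, "yhat")
    _check_same_shape(y, yh)
    total = int(y.sum()) + int(yh.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((y & yh).sum()) / total


def intersection_over_union(y, yhat) -> float:
    y = _as_binary_mask(y, "y")
    yh = _as_binary_mask(yhat, "yhat")
    _check_same_shape(y, yh)
    union = int((y | yh).sum())
    if union == 0:
        return 1.0
    return int((y & yh).sum()) / union


def hausdorff_distance(y, yhat) -> float:
    """Symmetric Hausdorff distance between foreground pixel sets, in pixels."""
    y = _as_binary_mask(y, "y")
    yh = _as_binary_mask(yhat, "yhat")
    _check_same_shape(y, yh)
    py = np.argwhere(y)
    ph = np.argwhere(yh)
    if len(py) == 0 and len(ph) == 0:
        return 0.0
    if len(py) == 0 or len(ph) == 0:
        h, w = y.shape
        return math.hypot(h - 1, w - 1)
    forward = directed_hausdorff(py.astype(float), ph.astype(float))[0]
    backward = directed_hausdorff(ph.astype(float), py.astype(float))[0]
    return max(forward, backward)


def binarize(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map: 1 where p >= threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must lie in (0, 1), got {threshold}")
    p = np.asarray(probabilities, dtype=float)
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValidationError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(np.uint8)


# ----------------------------------------------------------------------
@dataclass
class MetricsReport:
    """Per-sample DC/IoU/HD rows plus mean ± std aggregates."""

    per_sample: list[tuple[str, float, float, float]]

    @property
    def aggregate(self) -> dict[str, tuple[float, float]]:
        arr = np.array([[dc, iou, hd] for _, dc, iou, hd in self.per_sample], dtype=float)
        out = {}
        for i, name in enumerate(("dc", "iou", "hd")):
            col = arr[:, i]
            out[name] = (float(col.mean()), float(col.std(ddof=0)))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_sample, columns=["id", "dc", "iou", "hd"])

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(Path(path), index=False)

    def save_json(self, path) -> None:
        agg = {k: {"mean": m, "std": s} for k, (m, s) in self.aggregate.items()}
        Path(path).write_text(json.dumps(agg, indent=2))

    def format_aggregate(self) -> str:
        """"mean ± std" rows, one per metric."""
        agg = self.aggregate
        return "\n".join(
            f"{name.upper():>4}: {m:.4g} ± {s:.4g}" for name, (m, s) in agg.items()
        )


def score_pair(sample_id: str, y, yhat) -> tuple[str, float, float, float]:
    return (sample_id, dice_coefficient(y, yhat), intersection_over_union(y, yhat),
            hausdorff_distance(y, yhat))
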