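"""Pixel-level binary classification of GTAs against histology.

The test population is the whole tumor area on histology (WTA_H): viable
pixels are condition-positive, necrotic pixels condition-negative, and the
surrounding normal tissue and air are excluded from the test population.
A pixel tests positive when the GTA covers it. Three headline metrics per
(pair, threshold):

* sensitivity  = TP / (TP + FN)   — viable tumor covered by the GTA,
* specificity  = TN / (TN + FP)   — necrotic tumor excluded by the GTA,
* GTA_OE/WTA_H = OE / |WTA_H|     — GTA spill outside the tumor, relative
  to the tumor's histological area (may exceed 1).

Because all thresholds on one slice are single values of the same image,
they trace a single ROC curve per image pair; its area is computed through
the Gini coefficient, G = 2 AUC - 1, evaluated with the trapezoidal
identity so that it coincides exactly with trapezoidal integration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .contouring import GrossTumorArea, ThresholdSpec, make_gta
from .registration import RegisteredPair

__all__ = ["ConfusionSummary", "RocCurve", "classify_pair", "roc_for_pair", "auc_gini"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionSummary:
    """Pixel counts of one GTA tested on one registered pair."""

    tp_px: int
    fn_px: int
    tn_px: int
    fp_px: int
    oe_px: int
    wta_px: int

    @property
    def sensitivity(self) -> float:
        pos = self.tp_px + self.fn_px
        return self.tp_px / pos if pos else float("nan")

    @property
    def specificity(self) -> float:
        neg = self.tn_px + self.fp_px
        return self.tn_px / neg if neg else float("nan")

    @property
    def oe_ratio(self) -> float:
        return self.oe_px / self.wta_px if self.wta_px else float("nan")


@dataclass
class RocCurve:
    points: np.ndarray  # (k, 2) of (fpr, tpr), anchors included, sorted
    auc: float
    section_id: str
    defined: bool = True


def classify_pair(pair: RegisteredPair, gta: GrossTumorArea) -> ConfusionSummary:
    """Exact set-intersection confusion counts restricted to WTA_H."""
    mask = np.asarray(gta.mask, dtype=bool)
    if mask.shape != pair.labels_coarse.shape:
        raise ValueError("GTA mask shape does not match the registered pair")
    viable, necrotic = pair.viable_px, pair.necrotic_px
    return ConfusionSummary(
        tp_px=int((mask & viable).sum()),
        fn_px=int((~mask & viable).sum()),
        tn_px=int((~mask & necrotic).sum()),
        fp_px=int((mask & necrotic).sum()),
        oe_px=int((mask & pair.outside_px).sum()),
        wta_px=int(pair.wta_px.sum()),
    )


def auc_gini(points: np.ndarray) -> float:
    """Area under a (fpr, tpr) curve via the Gini coefficient.

    With points sorted by fpr and anchored at (0,0) and (1,1),
    ``G = sum_k (x_k - x_{k-1}) (y_k + y_{k-1}) - 1`` and ``AUC = (G+1)/2``,
    which is exactly the trapezoidal area.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (k, 2)")
    x, y = pts[:, 0], pts[:, 1]
    if np.any(np.diff(x) < 0):
        raise ValueError("points must be sorted by fpr")
    gini = float(np.sum(np.diff(x) * (y[1:] + y[:-1]))) - 1.0
    return (gini + 1.0) / 2.0


def roc_for_pair(pair: RegisteredPair, spectrum: list[ThresholdSpec]) -> RocCurve:
    """One ROC curve per image pair from the pooled threshold spectrum.

    Thresholds from all methods are pooled and deduplicated by absolute
    counts. Pairs lacking a viable or a necrotic class have no defined
    curve; they are flagged and excluded from aggregation by the caller.
    """
    if not spectrum:
        raise ValueError("spectrum is empty")
    n_pos = int(pair.viable_px.sum())
    n_neg = int(pair.necrotic_px.sum())
    if n_pos == 0 or n_neg == 0:
        logger.info(
            "pair %s: ROC undefined (viable=%d, necrotic=%d pixels)",
            pair.section_id,
            n_pos,
            n_neg,
        )
        return RocCurve(
            points=np.array([[0.0, 0.0], [1.0, 1.0]]),
            auc=float("nan"),
            section_id=pair.section_id,
            defined=False,
        )
    thresholds = sorted({s.absolute_counts for s in spectrum})
    pts = [(0.0, 0.0), (1.0, 1.0)]
    for t in thresholds:
        c = classify_pair(
            pair, make_gta(pair.pet_slice, _bare_spec(t), pair.section_id)
        )
        pts.append((1.0 - c.specificity, c.sensitivity))
    arr = np.array(sorted(pts))  # lexicographic: fpr, then tpr
    return RocCurve(points=arr, auc=auc_gini(arr), section_id=pair.section_id)


def _bare_spec(absolute: float) -> ThresholdSpec:
    return ThresholdSpec(method="cmax_pct", parameter=1.0, absolute_counts=absolute)
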