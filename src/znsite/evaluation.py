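"""Benchmarking protocol: radius-based TP/FP/FN matching with clustering,
precision-recall curves with AUC, and localization (MAD) statistics."""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractViolationError


@dataclass
class IonPrediction:
    structure_id: str
    coord: np.ndarray
    p: float = 1.0
    s: float = 0.0

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)


@dataclass
class GroundTruthSite:
    structure_id: str
    metal: str
    coord: np.ndarray

    def __post_init__(self) -> None:
        self.coord = np.asarray(self.coord, dtype=float)
        if not np.all(np.isfinite(self.coord)):
            raise ContractViolationError("truth coordinate must be finite")


def as_ion_predictions(predictions: Sequence) -> list[IonPrediction]:
    """Convert pipeline Prediction objects (or pass through IonPrediction)."""
    out = []
    for p in predictions:
        if isinstance(p, IonPrediction):
            out.append(p)
        else:
            out.append(
                IonPrediction(p.structure_id, p.zinc_coord, p.score.p, p.score.s)
            )
    return out


@dataclass
class MatchResult:
    radius: float
    tp_sites: list[GroundTruthSite] = field(default_factory=list)
    n_pred_within: int = 0
    fp_clusters: int = 0
    fn: int = 0
    tp_distances: list[float] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_sites)


def match_predictions(
    predictions: Sequence, truths: Sequence[GroundTruthSite], radius: float
) -> MatchResult:
    """A truth site is a TP iff some same-structure prediction lies within
    the radius (multiple such predictions count once toward TP but all
    toward n_pred_within).  Unmatched predictions are greedily clustered
    (best score first, absorb everything within radius) and each cluster
    counts one FP."""
    preds = as_ion_predictions(predictions)
    result = MatchResult(radius=radius)
    truths_by_sid: dict[str, list[GroundTruthSite]] = {}
    for t in truths:
        truths_by_sid.setdefault(t.structure_id, []).append(t)
    preds_by_sid: dict[str, list[IonPrediction]] = {}
    for p in preds:
        preds_by_sid.setdefault(p.structure_id, []).append(p)

    unmatched: list[IonPrediction] = []
    for sid, sid_preds in preds_by_sid.items():
        sid_truths = truths_by_sid.get(sid, [])
        for pred in sid_preds:
            dists = [float(np.linalg.norm(pred.coord - t.coord)) for t in sid_truths]
            if dists and min(dists) <= radius:
                result.n_pred_within += 1
                result.tp_distances.append(min(dists))
            else:
                unmatched.append(pred)
    for sid, sid_truths in truths_by_sid.items():
        sid_preds = preds_by_sid.get(sid, [])
        for truth in sid_truths:
            hit = any(
                float(np.linalg.norm(p.coord - truth.coord)) <= radius
                for p in sid_preds
            )
            if hit:
                result.tp_sites.append(truth)
            else:
                result.fn += 1

    # greedy FP clustering per structure, seeded by best score quality
    unmatched_by_sid: dict[str, list[IonPrediction]] = {}
    for p in unmatched:
        unmatched_by_sid.setdefault(p.structure_id, []).append(p)
    for sid in sorted(unmatched_by_sid):
        pool = sorted(unmatched_by_sid[sid], key=lambda p: (-p.p, p.s))
        while pool:
            seed = pool.pop(0)
            result.fp_clusters += 1
            pool = [
                p for p in pool
                if float(np.linalg.norm(p.coord - seed.coord)) > radius
            ]
    return result


@dataclass
class PRCurve:
    points: list[tuple[float, float, float]]  # (threshold, precision, recall)
    auc: float


def pr_curve(
    predictions: Sequence, truths: Sequence[GroundTruthSite], radius: float
) -> PRCurve:
    """Sweep the distinct prediction probabilities as thresholds; integrate
    precision over unique recall values by the trapezoid rule (anchored at
    recall 0 with the highest-threshold precision)."""
    if not truths:
        raise ContractViolationError("PR curve undefined with zero truth sites")
    preds = as_ion_predictions(predictions)
    if not preds:
        return PRCurve(points=[], auc=0.0)
    n_truth = len(truths)
    thresholds = sorted({p.p for p in preds}, reverse=True)
    points = []
    for thr in thresholds:
        subset = [p for p in preds if p.p >= thr]
        m = match_predictions(subset, truths, radius)
        denom = m.tp + m.fp_clusters
        precision = m.tp / denom if denom else 0.0
        recall = m.tp / n_truth
        points.append((thr, precision, recall))
    # integrate over unique recalls, keeping the best precision at each
    best_at_recall: dict[float, float] = {}
    for _, prec, rec in points:
        best_at_recall[rec] = max(best_at_recall.get(rec, 0.0), prec)
    recalls = sorted(best_at_recall)
    precisions = [best_at_recall[r] for r in recalls]
    if recalls and recalls[0] > 0.0:
        recalls = [0.0] + recalls
        precisions = [precisions[0]] + precisions
    auc = float(np.trapezoid(precisions, recalls)) if len(recalls) > 1 else 0.0
    return PRCurve(points=points, auc=auc)


@dataclass
class MadStats:
    mean: float
    sd: float
    median: float
    iqr: tuple[float, float]


def mad_stats(tp_distances: Sequence[float]) -> MadStats:
    """Mean +/- sample sd, median, and 25-75 percentile range (linear
    interpolation) of prediction-to-truth distances."""
    d = np.asarray(tp_distances, dtype=float)
    if d.size == 0:
        raise ContractViolationError("no distances supplied")
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    q25, q75 = np.percentile(d, [25, 75], method="linear")
    return MadStats(
        mean=float(np.mean(d)), sd=sd, median=float(np.median(d)),
        iqr=(float(q25), float(q75)),
    )


def selectivity_panel(
    predictions: Sequence,
    truths_by_metal: dict[str, Sequence[GroundTruthSite]],
    radius: float,
    min_p: float = 0.15,
) -> dict[str, dict]:
    """Per-metal precision/recall of the (thresholded) predictions against
    each metal's truth sites.  Metals with no truth sites are omitted."""
    preds = [p for p in as_ion_predictions(predictions) if p.p >= min_p]
    panel = {}
    for metal, truths in truths_by_metal.items():
        truths = list(truths)
        if not truths:
            continue
        m = match_predictions(preds, truths, radius)
        denom = m.tp + m.fp_clusters
        panel[metal] = {
            "tp": m.tp,
            "fn": m.fn,
            "fp": m.fp_clusters,
            "precision": m.tp / denom if denom else 0.0,
            "recall": m.tp / len(truths),
            "mad": None if not m.tp_distances else mad_stats(m.tp_distances).__dict__,
        }
    return panel


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_truth_csv(path) -> list[GroundTruthSite]:
    """Truth CSV schema: structure_id, metal, x, y, z."""
    truths = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            truths.append(
                GroundTruthSite(
                    structure_id=row["structure_id"],
                    metal=row["metal"],
                    coord=np.array(
                        [float(row["x"]), float(row["y"]), float(row["z"])]
                    ),
                )
            )
    return truths


def read_predictions_csv(path) -> list[IonPrediction]:
    """Read the pipeline's prediction CSV back into ion predictions."""
    preds = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            preds.append(
                IonPrediction(
                    structure_id=row["structure_id"],
                    coord=np.array(
                        [float(row["zinc_x"]), float(row["zinc_y"]), float(row["zinc_z"])]
                    ),
                    p=float(row["p"]),
                    s=float(row["s"]),
                )
            )
    return preds
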