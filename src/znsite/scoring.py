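"""Score features, composite score, and probability calibration.

The composite score is a case-dependent linear combination of three
features: the coordination-distance RMSD, the template-superposition RMSD,
and (for His-containing sites) an imidazole orientation score.  Raw scores
are mapped to probabilities with a two-parameter logistic (Platt scaling);
the shipped default calibration interpolates exactly through two published
anchor points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ContractViolationError, DegenerateFitError

#: ideal metal-ligand coordination distance, Å
IDEAL_DISTANCE = 2.15
#: ideal distance for the cysteine sulfur, Å
IDEAL_DISTANCE_CYS_S = 2.32


def ideal_distance(atom_name: str) -> float:
    return IDEAL_DISTANCE_CYS_S if atom_name == "SG" else IDEAL_DISTANCE


# ---------------------------------------------------------------------------
# feature scores
# ---------------------------------------------------------------------------

def drmsd(distances: Sequence[float], ideals: Sequence[float]) -> float:
    """Root-mean-square deviation of coordination distances from per-ligand
    ideal values."""
    distances = np.asarray(distances, dtype=float)
    ideals = np.asarray(ideals, dtype=float)
    if distances.shape != ideals.shape:
        raise ContractViolationError("distances and ideals differ in length")
    if distances.size < 3:
        raise ContractViolationError("need at least 3 coordination distances")
    return float(np.sqrt(np.mean((distances - ideals) ** 2)))


def his_angles_score(
    alphas: Sequence[float],
    betas: Sequence[float],
    alpha_ideal: float = 0.0,
    beta_ideal: float = 0.0,
) -> float:
    """RMS of the out-of-plane angles plus RMS of the in-plane angles, both
    taken as deviations from their ideal values (degrees)."""
    alphas = np.asarray(alphas, dtype=float)
    betas = np.asarray(betas, dtype=float)
    if alphas.size == 0 or alphas.shape != betas.shape:
        raise ContractViolationError("need matching, non-empty angle lists")
    a_rms = float(np.sqrt(np.mean((alphas - alpha_ideal) ** 2)))
    b_rms = float(np.sqrt(np.mean((betas - beta_ideal) ** 2)))
    return a_rms + b_rms


# ---------------------------------------------------------------------------
# composite score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoreParameters:
    b1: float
    b2: float
    b3: float
    c: float
    case: str


#: optimized per-case weights (b1, b2, b3, c)
SCORE_PARAMETERS: dict[str, ScoreParameters] = {
    "his_4plus": ScoreParameters(12.3, 5.0, 0.3, 0.0, "his_4plus"),
    "his_3": ScoreParameters(13.8, 0.7, 0.2, 8.1, "his_3"),
    "nohis_4plus": ScoreParameters(13.8, 14.5, 0.0, 5.5, "nohis_4plus"),
    "nohis_3": ScoreParameters(12.9, 1.6, 0.0, 14.4, "nohis_3"),
}


def dispatch_case(has_his: bool, n_residues: int) -> ScoreParameters:
    if n_residues < 3:
        raise ContractViolationError("sites have at least 3 residues")
    key = ("his_" if has_his else "nohis_") + ("4plus" if n_residues >= 4 else "3")
    return SCORE_PARAMETERS[key]


def composite_score(
    drmsd_value: float,
    trmsd_value: float,
    his_score: float | None,
    params: ScoreParameters,
) -> float:
    """s = b1*dRMSD + b2*TRMSD + b3*HisAnglesScore + c (lower is better)."""
    his_term = 0.0
    if params.b3 != 0.0:
        if his_score is None:
            raise ContractViolationError(
                f"case {params.case} requires a His angles score"
            )
        his_term = params.b3 * his_score
    return params.b1 * drmsd_value + params.b2 * trmsd_value + his_term + params.c


@dataclass
class ScoreBreakdown:
    drmsd: float
    trmsd: float
    alpha_rms: float | None
    beta_rms: float | None
    his_angles_score: float | None
    s: float
    p: float
    template_id: str
    case: str


# ---------------------------------------------------------------------------
# Platt calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Logistic score-to-probability map p = 1/(1 + exp(-(A*s + B)))."""

    A: float
    B: float


def platt_probability(s, model: CalibrationModel):
    z = np.clip(model.A * np.asarray(s, dtype=float) + model.B, -700, 700)
    p = 1.0 / (1.0 + np.exp(-z))
    return float(p) if np.isscalar(s) or np.ndim(s) == 0 else p


def fit_from_anchors(anchor1: tuple[float, float], anchor2: tuple[float, float]) -> CalibrationModel:
    """Exact two-point logistic interpolation through (s, p) anchors."""
    (s1, p1), (s2, p2) = anchor1, anchor2
    if s1 == s2:
        raise DegenerateFitError("anchors share the same score")
    z1 = math.log(p1 / (1.0 - p1))
    z2 = math.log(p2 / (1.0 - p2))
    a = (z2 - z1) / (s2 - s1)
    b = z1 - a * s1
    return CalibrationModel(A=a, B=b)


#: anchors (s=3.36, p=0.996) and (s=15.32, p=0.30) give A ~= -0.532, B ~= 7.31
DEFAULT_CALIBRATION_ANCHORS = ((3.36, 0.996), (15.32, 0.30))
DEFAULT_CALIBRATION = fit_from_anchors(*DEFAULT_CALIBRATION_ANCHORS)


def _nll(params: np.ndarray, scores: np.ndarray, labels: np.ndarray) -> float:
    a, b = params
    z = np.clip(a * scores + b, -700, 700)
    p = 1.0 / (1.0 + np.exp(-z))
    p = np.clip(p, 1e-15, 1 - 1e-15)
    return float(-np.mean(labels * np.log(p) + (1 - labels) * np.log(1 - p)))


def fit_platt(
    scores: Sequence[float],
    labels: Sequence[int],
    split_seed: int = 0,
    train_fraction: float = 0.8,
    bound: float = 50.0,
):
    """Fit (A, B) by minimizing the negative log-likelihood on a random
    80/20 train split.  Returns (model, validation_scores, validation_labels).
    """
    from scipy.optimize import minimize

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.size == 0 or scores.shape != labels.shape:
        raise ContractViolationError("scores and labels must align")
    if len(np.unique(labels)) < 2:
        raise DegenerateFitError("both classes required to fit calibration")

    rng = np.random.default_rng(split_seed)
    order = rng.permutation(scores.size)
    n_train = max(2, int(round(train_fraction * scores.size)))
    train, valid = order[:n_train], order[n_train:]
    if len(np.unique(labels[train])) < 2:  # degenerate split: fall back to all
        train = order
        valid = np.array([], dtype=int)

    pos, neg = scores[train][labels[train] == 1], scores[train][labels[train] == 0]
    if pos.max() < neg.min() or neg.max() < pos.min():
        warnings.warn(
            "perfectly separated scores: the unregularized slope is unbounded "
            "(known Platt pathology); fit kept within optimizer bounds",
            RuntimeWarning,
            stacklevel=2,
        )
    res = minimize(
        _nll,
        x0=np.array([-1.0, 0.0]),
        args=(scores[train], labels[train]),
        method="L-BFGS-B",
        bounds=[(-bound, bound), (-10 * bound, 10 * bound)],
    )
    a, b = res.x
    return CalibrationModel(A=float(a), B=float(b)), scores[valid], labels[valid]


# ---------------------------------------------------------------------------
# calibration quality metrics
# ---------------------------------------------------------------------------

def brier_score(probs: Sequence[float], labels: Sequence[int]) -> float:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.size == 0 or probs.shape != labels.shape:
        raise ContractViolationError("probs and labels must align and be non-empty")
    return float(np.mean((probs - labels) ** 2))


def log_loss(probs: Sequence[float], labels: Sequence[int], clip: float = 1e-15) -> float:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.size == 0 or probs.shape != labels.shape:
        raise ContractViolationError("probs and labels must align and be non-empty")
    probs = np.clip(probs, clip, 1.0 - clip)
    return float(-np.mean(labels * np.log(probs) + (1 - labels) * np.log(1 - probs)))


# ---------------------------------------------------------------------------
# threshold selection
# ---------------------------------------------------------------------------

def f_score(precision: float, recall: float, beta: float = 1.0) -> float:
    denom = beta * beta * precision + recall
    if denom == 0:
        return 0.0
    return (1 + beta * beta) * precision * recall / denom


@dataclass
class ThresholdReport:
    best_f1: float
    best_f1_thresholds: list[float] = field(default_factory=list)
    best_fbeta: float = 0.0
    beta: float = 2.0
    best_fbeta_thresholds: list[float] = field(default_factory=list)


def select_thresholds(
    pr_points: Sequence[tuple[float, float, float]], beta: float = 2.0
) -> ThresholdReport:
    """Given (threshold, precision, recall) points, report the maxima of F1
    and F-beta and every threshold attaining them."""
    if not pr_points:
        raise ContractViolationError("no PR points supplied")
    f1s = [f_score(p, r, 1.0) for (_, p, r) in pr_points]
    fbs = [f_score(p, r, beta) for (_, p, r) in pr_points]
    best_f1, best_fb = max(f1s), max(fbs)
    eps = 1e-12
    return ThresholdReport(
        best_f1=best_f1,
        best_f1_thresholds=[t for (t, _, _), f in zip(pr_points, f1s) if f >= best_f1 - eps],
        best_fbeta=best_fb,
        beta=beta,
        best_fbeta_thresholds=[t for (t, _, _), f in zip(pr_points, fbs) if f >= best_fb - eps],
    )
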