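"""Discrimination metrics, binarization thresholds, and binary range maps.

Model skill is measured against held-out pseudo-absences (presence-background
evaluation; no true absences exist). AUC is the rank-based probability that a
presence outranks a background point (ties count one half); TSS is
sensitivity + specificity - 1 at a chosen cutoff. Continuous suitability maps
become binary range maps through one of three ROC-derived threshold rules:

- ``SensEqSpec``    : minimize |sensitivity - specificity|
- ``MaxSensSpec``   : maximize sensitivity + specificity
- ``MinROCdist``    : minimize the distance of the ROC point to (0, 1)

A cell (or point) is predicted present when its score is >= the threshold.
Ties between equally good candidate thresholds are broken toward the lower
threshold, i.e. toward higher sensitivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .synthetic_landscape import GridGeometry, OccurrenceTable
from .sdm_core import SuitabilityMap

__all__ = [
    "THRESHOLD_RULES",
    "BinaryMap",
    "EvalScores",
    "roc_auc",
    "tss",
    "sensitivity_specificity",
    "select_threshold",
    "binarize",
    "model_sensitivity",
    "aggregate_scores",
]

THRESHOLD_RULES = ("SensEqSpec", "MaxSensSpec", "MinROCdist")


@dataclass(frozen=True)
class BinaryMap:
    """Binary (0/1) range map; NaN marks nodata cells."""

    scenario_id: str
    values: np.ndarray
    threshold_rule: str = ""
    threshold_value: float = np.nan

    def __post_init__(self) -> None:
        v = self.values[np.isfinite(self.values)]
        if v.size and not np.all(np.isin(v, (0.0, 1.0))):
            raise ValueError("binary map values must be 0 or 1 on valid cells")

    @property
    def n_suitable(self) -> int:
        return int(np.nansum(self.values))

    def valid(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class EvalScores:
    """Cross-validation evaluation summary for one model type."""

    model_type: str  # {species, core, disjunct, aggregate}
    auc: np.ndarray  # per run
    tss: np.ndarray  # per run

    @property
    def auc_mean(self) -> float:
        return float(np.mean(self.auc))

    @property
    def auc_sd(self) -> float:
        return float(np.std(self.auc, ddof=1)) if len(self.auc) > 1 else 0.0

    @property
    def tss_mean(self) -> float:
        return float(np.mean(self.tss))

    @property
    def tss_sd(self) -> float:
        return float(np.std(self.tss, ddof=1)) if len(self.tss) > 1 else 0.0


def _check_two_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes (presence and background) must be present")


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(presence score > background score), ties = 1/2.

    Equal to the Mann-Whitney pairwise-comparison fraction; invariant under
    any strictly monotone transform of the scores.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    _check_two_classes(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tss(confusion: tuple[float, float, float, float]) -> float:
    """True skill statistic from a (TP, FP, TN, FN) confusion tuple."""
    tp, fp, tn, fn = confusion
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("TSS undefined with an empty class")
    return tp / (tp + fn) + tn / (tn + fp) - 1.0


def sensitivity_specificity(scores: np.ndarray, labels: np.ndarray,
                            threshold: float) -> tuple[float, float]:
    """(sensitivity, specificity) of the rule 'present iff score >= threshold'."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    _check_two_classes(labels)
    pred = scores >= threshold
    sens = np.mean(pred[labels])
    spec = np.mean(~pred[~labels])
    return float(sens), float(spec)


def _candidate_curve(scores: np.ndarray, labels: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All candidate thresholds with their sensitivity/specificity.

    Candidates are the unique score values plus a sentinel above the maximum
    (the predict-nothing cut); the minimum score already yields the
    predict-everything cut. Returned in increasing threshold order.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    cand = np.append(uniq, uniq[-1] + 1.0)
    n1, n0 = labels.sum(), (~labels).sum()
    order = np.argsort(scores, kind="stable")
    s_sorted, l_sorted = scores[order], labels[order]
    # presences/background strictly below each candidate
    below = np.searchsorted(s_sorted, cand, side="left")
    pres_below = np.concatenate([[0], np.cumsum(l_sorted)])[below]
    bg_below = below - pres_below
    sens = (n1 - pres_below) / n1
    spec = bg_below / n0
    return cand, sens, spec


def select_threshold(scores: np.ndarray, labels: np.ndarray, rule: str) -> float:
    """Optimal binarization threshold under one of the three ROC rules.

    Scans every candidate cutoff (unique scores plus sentinels) and returns
    the optimizer; ties break toward the lower threshold (higher sensitivity).
    """
    if rule not in THRESHOLD_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {THRESHOLD_RULES}")
    cand, sens, spec = _candidate_curve(scores, labels)
    if rule == "SensEqSpec":
        crit = np.abs(sens - spec)
    elif rule == "MaxSensSpec":
        crit = -(sens + spec)
    else:  # MinROCdist
        crit = np.sqrt((1 - sens) ** 2 + (1 - spec) ** 2)
    return float(cand[int(np.argmin(crit))])  # argmin takes the first = lowest cut


def binarize(smap: SuitabilityMap, threshold_value: float,
             threshold_rule: str = "") -> BinaryMap:
    """Binary map: cell = 1 iff suitability >= threshold; nodata preserved."""
    if not np.isfinite(threshold_value):
        raise ValueError("threshold must be finite")
    v = np.where(np.isfinite(smap.values),
                 (smap.values >= threshold_value).astype(float), np.nan)
    return BinaryMap(smap.scenario_id, v, threshold_rule, float(threshold_value))


def model_sensitivity(binary: BinaryMap, occ: OccurrenceTable,
                      geometry: GridGeometry) -> float:
    """Percentage of occupied sites predicted suitable by a binary map."""
    if len(occ) == 0:
        raise ValueError("sensitivity undefined for an empty occurrence set")
    rows, cols = occ.rowcols(geometry)
    vals = binary.values[rows, cols]
    return float(100.0 * np.nansum(vals == 1.0) / len(occ))


def aggregate_scores(core: EvalScores, disjunct: EvalScores) -> EvalScores:
    """Aggregate-model scores: per-run mean of the core and disjunct scores."""
    return EvalScores("aggregate",
                      auc=(core.auc + disjunct.auc) / 2.0,
                      tss=(core.tss + disjunct.tss) / 2.0)
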