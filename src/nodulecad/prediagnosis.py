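"""Multilevel rule-based screening of candidate regions.

A candidate is declared a suspected nodule only if it passes, in order,
five feature gates: large enough (``S_R >= T_S``, rejecting sub-3 mm
lesions), round enough (``C_R >= T_C``, rejecting elongated vessels), not
too bright (``GM <= T_GM``, rejecting vessels perpendicular to the slice),
gray-heterogeneous (``GE >= T_GE``) and sufficiently burred
(``MBR >= T_MBR``, smooth-margined mimics are rejected).  Evaluation is
short-circuit: the first failing gate is recorded as the rejection reason.

The shipped default cutoffs are T_S = 30, T_C = 0.6, T_GM = 196,
T_GE = 3.5, T_MBR = 0.16; suspected nodules with ``S_R`` >= 300
(approximately > 10 mm diameter) are additionally flagged as large.

Detection quality is summarized by sensitivity ``F_se = TP/(TP+FN)``,
specificity ``F_sp = TN/(FP+TN)`` (identically 0 in this framing because a
non-nodule is defined as negative and TN = 0), and accuracy
``F_a = TP/(TP+TN+FP+FN)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .features import RegionFeatures

__all__ = [
    "ClassificationError",
    "ThresholdSet",
    "Detection",
    "ConfusionMetrics",
    "DEFAULT_THRESHOLDS",
    "classify_region",
    "flag_large",
    "classify_all",
    "evaluate_detection",
    "calibrate_thresholds",
]

FEATURE_ORDER = ("S", "C", "GM", "GE", "MBR")
_ATTR = {"S": "s_r", "C": "c_r", "GM": "gm", "GE": "ge", "MBR": "mbr"}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdSet:
    """Feature cutoffs, comparison directions and weights of the criterion."""

    t_s: float = 30.0
    t_c: float = 0.6
    t_gm: float = 196.0
    t_ge: float = 3.5
    t_mbr: float = 0.16
    directions: dict = field(default_factory=lambda: {
        "S": ">=", "C": ">=", "GM": "<=", "GE": ">=", "MBR": ">="})
    weights: dict = field(default_factory=lambda: {
        "S": 0.2, "C": 0.2, "GM": 0.2, "GE": 0.2, "MBR": 0.2})
    large_area: float = 300.0

    def validate(self) -> None:
        if abs(sum(self.weights.values()) - 1.0) > 1e-9:
            raise ClassificationError("threshold weights must sum to 1")
        if any(d not in (">=", "<=") for d in self.directions.values()):
            raise ClassificationError("directions must be '>=' or '<='")

    def cutoff(self, name: str) -> float:
        return {"S": self.t_s, "C": self.t_c, "GM": self.t_gm,
                "GE": self.t_ge, "MBR": self.t_mbr}[name]

    def with_cutoff(self, name: str, value: float) -> "ThresholdSet":
        key = {"S": "t_s", "C": "t_c", "GM": "t_gm",
               "GE": "t_ge", "MBR": "t_mbr"}[name]
        return replace(self, **{key: value})


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass
class Detection:
    suspected: bool
    rejection_reason: str | None    # failing gate, e.g. "C"
    large: bool
    centroid: tuple[float, float]
    centroid_mm: tuple[float, ...] | None = None
    features: RegionFeatures | None = None


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    f_se: float
    f_sp: float
    f_a: float
    f_ce: float | None = None       # seconds per image, reported only


def _passes(value: float, cutoff: float, direction: str) -> bool:
    return value >= cutoff if direction == ">=" else value <= cutoff


def classify_region(f: RegionFeatures,
                    t: ThresholdSet = DEFAULT_THRESHOLDS) -> Detection:
    """Apply the five gates in order; short-circuit on the first failure."""
    t.validate()
    for name in FEATURE_ORDER:
        value = getattr(f, _ATTR[name])
        if not _passes(value, t.cutoff(name), t.directions[name]):
            return Detection(suspected=False, rejection_reason=name,
                             large=False, centroid=f.centroid, features=f)
    return Detection(suspected=True, rejection_reason=None,
                     large=flag_large(f, t), centroid=f.centroid, features=f)


def flag_large(f: RegionFeatures, t: ThresholdSet = DEFAULT_THRESHOLDS) -> bool:
    """Large-nodule flag: area at or above the large-area cutoff."""
    return f.s_r >= t.large_area


def classify_all(features: list[RegionFeatures],
                 t: ThresholdSet = DEFAULT_THRESHOLDS) -> list[Detection]:
    return [classify_region(f, t) for f in features]


def evaluate_detection(predicted: list, truth: list, match_radius: float = 5.0
                       ) -> ConfusionMetrics:
    """Greedy nearest-first centroid matching and the four metrics.

    ``predicted`` holds :class:`Detection` objects (only suspected-nodule
    entries count as positive calls) or bare centroids; ``truth`` holds the
    reference nodule centroids in the same coordinate frame.  A prediction
    within ``match_radius`` of an unmatched truth centroid is a TP;
    remaining predictions are FP, unmatched truths FN, and TN = 0 since a
    non-nodule is negative by definition.
    """
    def _centroid(p):
        return np.asarray(p.centroid if isinstance(p, Detection) else p, float)

    pos = [p for p in predicted
           if not isinstance(p, Detection) or p.suspected]
    if not pos and not truth:
        raise ClassificationError(
            "sensitivity undefined: no predictions and no truth nodules")
    pred_pts = [_centroid(p) for p in pos]
    truth_pts = [np.asarray(c, float) for c in truth]

    pairs = sorted(
        ((np.linalg.norm(p - q), i, j)
         for i, p in enumerate(pred_pts) for j, q in enumerate(truth_pts)),
        key=lambda x: x[0])
    used_p, used_t = set(), set()
    tp = 0
    for d, i, j in pairs:
        if d > match_radius:
            break
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp += 1
    fp = len(pred_pts) - tp
    fn = len(truth_pts) - tp
    tn = 0
    f_se = tp / (tp + fn) if (tp + fn) else 0.0
    f_sp = tn / (fp + tn) if (fp + tn) else 0.0
    f_a = tp / (tp + tn + fp + fn) if (tp + tn + fp + fn) else 0.0
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn,
                            f_se=f_se, f_sp=f_sp, f_a=f_a)


def _score(table: list[tuple[RegionFeatures, bool]], t: ThresholdSet
           ) -> tuple[float, float]:
    tp = fp = fn = 0
    for f, is_nodule in table:
        call = classify_region(f, t).suspected
        if call and is_nodule:
            tp += 1
        elif call and not is_nodule:
            fp += 1
        elif not call and is_nodule:
            fn += 1
    f_se = tp / (tp + fn) if (tp + fn) else 0.0
    f_a = tp / (tp + fp + fn) if (tp + fp + fn) else 0.0
    return f_se, f_a


def calibrate_thresholds(table: list[tuple[RegionFeatures, bool]],
                         weights: dict | None = None,
                         search_spec: dict | None = None,
                         base: ThresholdSet = DEFAULT_THRESHOLDS,
                         ) -> ThresholdSet:
    """Deterministic grid search for the five cutoffs on a labeled table.

    ``table`` is a list of (features, is_nodule) pairs containing both
    classes.  The base cutoffs are first rescaled by the feature weights
    (``T_i <- xi_i * T_i`` with the weights summing to 1), then every
    combination in ``search_spec`` (feature name -> candidate cutoffs) is
    scored by sensitivity with accuracy as the tie-break.  The returned set
    never scores below the unscaled base set, which competes in the search.
    """
    labels = {bool(is_nod) for _, is_nod in table}
    if labels != {True, False}:
        raise ClassificationError("calibration table needs both classes")
    if weights is not None:
        if abs(sum(weights.values()) - 1.0) > 1e-9:
            raise ClassificationError("weights must sum to 1")
        base_w = replace(base, weights=dict(weights))
        scaled = base_w
        for name in FEATURE_ORDER:
            scaled = scaled.with_cutoff(
                name, weights.get(name, 0.0) * base.cutoff(name) * len(weights))
    else:
        scaled = base

    if search_spec is None:
        search_spec = {
            name: [base.cutoff(name) * s for s in (0.5, 0.75, 1.0, 1.25, 1.5)]
            for name in FEATURE_ORDER}

    names = [n for n in FEATURE_ORDER if n in search_spec]
    candidates = [scaled, base]
    for combo in itertools.product(*(search_spec[n] for n in names)):
        t = scaled
        for name, value in zip(names, combo):
            t = t.with_cutoff(name, value)
        candidates.append(t)
    best = max(candidates, key=lambda t: _score(table, t))
    return best
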