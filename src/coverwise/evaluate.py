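"""Three-criteria accuracy assessment and scenario selection.

A classified map is judged three ways:

1. classical accuracy on validation pixels — Cohen's Kappa and the
   target-class F1 score;
2. the fraction of correctly labelled target pixels inside validation plots
   of each cover stratum (20-40, 50-70, 80-100 %), with the false-positive
   fraction over background validation plots as the overestimation signal;
3. zonal compatibility with field mapping inside a control square: pixel
   areas of TP/FP/TN/FN against the field-mapped patch outlines.

The zonal percentage convention is deliberately asymmetric: TP, FP and FN
are normalized by the control-area *species* area while TN is normalized by
the control-area *background* area, and values are rounded half-up.  Under
this convention TP% + FN% = 100 and FP% reads as "false-positive area as a
share of the true species area" — an overestimation ratio that can exceed
100 %.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classify import LABEL_TARGET, ClassifiedMap
from .sampling import STRATA, ReferencePolygon


class EvaluationError(ValueError):
    pass


# --------------------------------------------------------------------------
# pixel-count criteria
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(bool)
    y_pred = np.asarray(y_pred).astype(bool)
    return ConfusionCounts(tp=int(np.sum(y_true & y_pred)),
                           fp=int(np.sum(~y_true & y_pred)),
                           tn=int(np.sum(~y_true & ~y_pred)),
                           fn=int(np.sum(y_true & ~y_pred)))


def kappa(counts: ConfusionCounts) -> float:
    """Cohen's Kappa: chance-corrected agreement, in [-1, 1]."""
    n = counts.total
    if n == 0:
        raise EvaluationError("empty confusion counts")
    p_o = (counts.tp + counts.tn) / n
    p_e = ((counts.tp + counts.fn) * (counts.tp + counts.fp)
           + (counts.fp + counts.tn) * (counts.fn + counts.tn)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return (p_o - p_e) / (1.0 - p_e)


def f1(counts: ConfusionCounts) -> float:
    """F1 score of the target class."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        raise EvaluationError("F1 undefined: no target pixels in truth or prediction")
    return 2.0 * counts.tp / denom


def stratum_tp_fraction(cmap: ClassifiedMap,
                        validation: Sequence[ReferencePolygon]
                        ) -> tuple[dict[str, float], float]:
    """Correctly classified target-pixel percentage per cover stratum.

    Returns ({stratum -> percent}, background false-positive percent); a
    stratum with no validation plots is simply absent from the mapping.
    """
    per_stratum: dict[str, float] = {}
    for s in STRATA:
        polys = [p for p in validation
                 if p.klass == "target" and p.stratum == s]
        if not polys:
            continue
        pix = np.array([px for p in polys for px in p.pixels])
        lab = cmap.labels[pix[:, 0], pix[:, 1]]
        per_stratum[s] = 100.0 * float(np.mean(lab == LABEL_TARGET))
    bg = [p for p in validation if p.klass == "background"]
    if not bg:
        raise EvaluationError("validation set has no background plots")
    pix = np.array([px for p in bg for px in p.pixels])
    lab = cmap.labels[pix[:, 0], pix[:, 1]]
    background_fp_pct = 100.0 * float(np.mean(lab == LABEL_TARGET))
    return per_stratum, background_fp_pct


def map_area_percent(cmap: ClassifiedMap) -> float:
    """Share of valid map pixels labelled as the target species, in percent."""
    valid = cmap.valid_mask
    if not np.any(valid):
        raise EvaluationError("map contains no valid pixels")
    return 100.0 * float(np.mean(cmap.labels[valid] == LABEL_TARGET))


# --------------------------------------------------------------------------
# zonal compatibility with field mapping
# --------------------------------------------------------------------------

@dataclass
class ConfusionAreas:
    """Control-area confusion in m2 plus the asymmetric percentage columns."""

    control_species_area: float
    control_background_area: float
    tp_area: float
    fp_area: float
    tn_area: float
    fn_area: float
    tp_pct: int | None = None
    fp_pct: int | None = None
    tn_pct: int | None = None
    fn_pct: int | None = None
    tp_pct_1dp: float | None = None
    fp_pct_1dp: float | None = None
    tn_pct_1dp: float | None = None
    fn_pct_1dp: float | None = None


def _round_half_up(x: float, decimals: int = 0) -> float:
    scale = 10 ** decimals
    return math.floor(x * scale + 0.5) / scale


def confusion_percentages(areas: ConfusionAreas) -> ConfusionAreas:
    """Fill the percentage columns under the asymmetric normalization.

    TP, FP, FN are percentages of the control species area; TN is a
    percentage of the control background area.  Integer columns use half-up
    rounding; the 1-decimal variants serve report text.
    """
    sp, bg = areas.control_species_area, areas.control_background_area
    if sp <= 0:
        raise EvaluationError("control species area must be positive")
    if bg <= 0:
        raise EvaluationError("control background area must be positive")
    vals = {
        "tp": 100.0 * areas.tp_area / sp,
        "fp": 100.0 * areas.fp_area / sp,
        "fn": 100.0 * areas.fn_area / sp,
        "tn": 100.0 * areas.tn_area / bg,
    }
    for k, v in vals.items():
        setattr(areas, f"{k}_pct", int(_round_half_up(v)))
        setattr(areas, f"{k}_pct_1dp", _round_half_up(v, 1))
    return areas


def zonal_confusion(cmap: ClassifiedMap, truth_patches: Sequence,
                    control_area_polygon) -> ConfusionAreas:
    """Overlay the classified map with field-mapped patches in the control area.

    Pixels whose centres fall inside the control square are split by whether
    the centre lies within any field-mapped patch (species vs background
    zone) and by the map label, giving TP/FP/TN/FN areas as pixel counts
    times gsd^2.  TP + FN always equals the species zone area and FP + TN
    the background zone area.
    """
    from shapely import contains_xy
    from shapely.ops import unary_union
    from shapely.prepared import prep

    if control_area_polygon.area <= 0:
        raise EvaluationError("control area polygon has zero area")
    rows, cols = cmap.labels.shape
    rr, cc = np.nonzero(cmap.valid_mask)
    x, y = cmap.transform.pixel_center(rr, cc)
    in_control = contains_xy(control_area_polygon, x, y)
    rr, cc, x, y = rr[in_control], cc[in_control], x[in_control], y[in_control]
    if rr.size == 0:
        raise EvaluationError("control area contains no valid pixels")
    if truth_patches:
        union = unary_union(list(truth_patches))
        inside = contains_xy(union, x, y)
    else:
        inside = np.zeros(rr.size, dtype=bool)
    pred = cmap.labels[rr, cc] == LABEL_TARGET
    a = cmap.gsd ** 2
    counts = confusion_from_labels(inside, pred)
    return ConfusionAreas(
        control_species_area=float(np.sum(inside)) * a,
        control_background_area=float(np.sum(~inside)) * a,
        tp_area=counts.tp * a, fp_area=counts.fp * a,
        tn_area=counts.tn * a, fn_area=counts.fn * a)


# --------------------------------------------------------------------------
# reports and scenario selection
# --------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """All three criteria for one scenario run."""

    scenario: str
    kappa: float
    f1: float
    stratum_tp_pct: dict[str, float]
    background_fp_pct: float
    confusion_areas: ConfusionAreas
    map_area_pct: float | None = None

    def to_row(self) -> dict:
        ca = self.confusion_areas
        row = {"scenario": self.scenario, "kappa": self.kappa, "f1": self.f1,
               "background_fp_pct": self.background_fp_pct,
               "map_area_pct": self.map_area_pct}
        for s in STRATA:
            row[f"tp_pct_{s}"] = self.stratum_tp_pct.get(s)
        row.update({
            "control_species_m2": ca.control_species_area,
            "control_background_m2": ca.control_background_area,
            "tp_m2": ca.tp_area, "fp_m2": ca.fp_area,
            "tn_m2": ca.tn_area, "fn_m2": ca.fn_area,
            "tp_pct": ca.tp_pct, "fp_pct": ca.fp_pct,
            "tn_pct": ca.tn_pct, "fn_pct": ca.fn_pct,
        })
        return row


def criterion_winners(reports: Sequence[EvaluationReport]) -> dict[str, str]:
    """Best scenario under each of the three assessment criteria."""
    if not reports:
        raise EvaluationError("no reports to compare")

    def accuracy_score(r):
        return (r.kappa + r.f1) / 2.0

    def stratum_score(r):
        tps = [v for v in r.stratum_tp_pct.values()]
        return (np.mean(tps) if tps else 0.0) - r.background_fp_pct

    def field_key(r):
        return (r.confusion_areas.tp_pct, -r.confusion_areas.fp_pct)

    return {
        "accuracy": max(reports, key=accuracy_score).scenario,
        "stratum": max(reports, key=stratum_score).scenario,
        "field": max(reports, key=field_key).scenario,
    }


def majority_winner(winners: dict[str, str]) -> str:
    """Overall winner by majority vote; field compatibility breaks 3-way ties."""
    names = list(winners.values())
    for name in names:
        if names.count(name) >= 2:
            return name
    return winners["field"]


def select_best_scenario(reports: Sequence[EvaluationReport]
                         ) -> tuple[str, dict[str, str]]:
    """Per-criterion winners and the overall majority-vote choice."""
    if len(reports) < 2:
        raise EvaluationError("need at least two reports to select a winner")
    winners = criterion_winners(reports)
    return majority_winner(winners), winners


def reports_to_dataframe(reports: Sequence[EvaluationReport]):
    import pandas as pd

    return pd.DataFrame([r.to_row() for r in reports])
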