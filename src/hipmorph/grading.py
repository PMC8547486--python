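"""Ordinal grading and morphology classification.

Converts continuous measures into the ordinal grades and binary classes used
for radiographic hip osteoarthritis (rHOA) phenotyping:

* osteophyte areas (mm^2) at the lateral acetabulum, superolateral femoral
  head and inferomedial femoral head -> grades 0-3 via area cutpoints;
* height-adjusted mJSW -> joint-space-narrowing (JSN) grade 0-3 (smaller
  adjusted mJSW means a higher grade);
* alpha angle / LCEA -> cam (AA >= 60 deg), pincer (LCEA >= 45 deg) and
  acetabular dysplasia (LCEA < 25 deg);
* rHOA = grade >=1 JSN together with a grade >=1 osteophyte at any site; a
  stricter variant requires grade >=2 of each.

Cutpoints can be supplied in configuration or calibrated against
semi-quantitative reference grades by ROC analysis (Youden's J by default).
The numeric defaults shipped here are synthetic placeholders on the same
scale as the study quantities, not published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Literal, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationError",
    "OsteophyteMarkup",
    "GradeThresholds",
    "GradingRecord",
    "HeightAdjustModel",
    "calibrate_threshold_roc",
    "calibrate_grade_thresholds",
    "grade_from_thresholds",
    "fit_height_adjustment",
    "height_adjust_mjsw",
    "classify_morphology",
    "classify_rhoa",
    "grade_cohort",
    "OSTEOPHYTE_SITES",
    "DEFAULT_OSTEOPHYTE_CUTPOINTS",
    "DEFAULT_JSN_CUTPOINTS",
]

OSTEOPHYTE_SITES = ("acetabular", "superior_femoral", "inferior_femoral")

# Synthetic default cutpoints (mm^2 areas; mm adjusted mJSW). The cutpoints
# actually used in the source study are not published, so these exist only to
# make ungraded configurations runnable; pipelines normally ROC-calibrate.
DEFAULT_OSTEOPHYTE_CUTPOINTS: Dict[str, Tuple[float, ...]] = {
    "acetabular": (0.5, 3.5, 9.0),
    "superior_femoral": (0.5, 3.5, 9.0),
    "inferior_femoral": (0.5, 3.5, 9.0),
}
DEFAULT_JSN_CUTPOINTS: Tuple[float, ...] = (1.5, 2.0, 2.5)


class CalibrationError(ValueError):
    """Raised when ROC threshold calibration is impossible (single-class reference)."""


@dataclass
class OsteophyteMarkup:
    participant_id: str
    area_acetabular_mm2: float = 0.0
    area_superior_femoral_mm2: float = 0.0
    area_inferior_femoral_mm2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("area_acetabular_mm2", "area_superior_femoral_mm2", "area_inferior_femoral_mm2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class GradeThresholds:
    """Cutpoints for one graded measure.

    ``direction`` is ``"greater"`` when larger values mean a higher grade
    (osteophyte areas; grade g iff value in [cut_g, cut_{g+1})) and
    ``"less"`` when smaller values mean a higher grade (adjusted mJSW -> JSN).
    """

    site: str
    cutpoints: Tuple[float, ...]
    direction: Literal["greater", "less"] = "greater"

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cutpoints)
        if not 1 <= len(cuts) <= 3:
            raise ValueError("cutpoints must contain 1-3 values")
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"cutpoints must be strictly increasing, got {cuts}")
        object.__setattr__(self, "cutpoints", cuts)


@dataclass
class GradingRecord:
    participant_id: str
    osteophyte_grades: Dict[str, int]
    jsn_grade: int
    rhoa: bool
    rhoa_grade2: bool
    cam: bool
    pincer: bool
    acetabular_dysplasia: bool


@dataclass(frozen=True)
class HeightAdjustModel:
    """Per-sex linear adjustment: adjusted = mjsw - slope * (height - mean_height)."""

    slope: Dict[str, float]
    mean_height: Dict[str, float]


# ---------------------------------------------------------------------------
# ROC threshold calibration
# ---------------------------------------------------------------------------


def calibrate_threshold_roc(continuous_values: Sequence[float],
                            reference_grades: Sequence[int],
                            boundary: int,
                            direction: Literal["greater", "less"] = "greater",
                            criterion: Literal["youden", "closest"] = "youden") -> float:
    """Cutpoint separating grade >= ``boundary`` from lower grades.

    Scans every midpoint between consecutive sorted unique values (plus the
    open ends) and returns the cutpoint maximising Youden's J
    (sensitivity + specificity - 1); ``criterion="closest"`` minimises the
    distance to the (0, 1) ROC corner instead.  Ties are broken toward the
    midpoint of the tied candidate interval, so perfectly separated classes
    yield the centre of the separating gap.
    """
    values = np.asarray(continuous_values, dtype=float)
    grades = np.asarray(reference_grades)
    if values.shape != grades.shape or values.ndim != 1:
        raise ValueError("values and reference grades must be 1-d and the same length")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite measure values")
    positive = grades >= boundary
    if positive.all() or (~positive).all():
        raise CalibrationError("both grade classes must be present to calibrate a threshold")
    sign = 1.0 if direction == "greater" else -1.0
    v = sign * values
    uniq = np.unique(v)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], cands, [uniq[-1] + 1.0]])
    pred = v[None, :] >= cands[:, None]  # (k, n)
    tp = (pred & positive).sum(axis=1)
    fp = (pred & ~positive).sum(axis=1)
    sens = tp / positive.sum()
    spec = 1.0 - fp / (~positive).sum()
    if criterion == "youden":
        score = sens + spec - 1.0
    elif criterion == "closest":
        score = -np.hypot(1.0 - sens, 1.0 - spec)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = score.max()
    tied = cands[np.isclose(score, best, rtol=0.0, atol=1e-12)]
    return float(sign * (tied.min() + tied.max()) / 2.0)


def calibrate_grade_thresholds(continuous_values: Sequence[float],
                               reference_grades: Sequence[int],
                               site: str,
                               direction: Literal["greater", "less"] = "greater",
                               max_grade: int = 3,
                               criterion: Literal["youden", "closest"] = "youden") -> GradeThresholds:
    """One ROC-calibrated cutpoint per attainable grade boundary (1..max_grade)."""
    grades = np.asarray(reference_grades)
    cuts = []
    for boundary in range(1, max_grade + 1):
        if (grades >= boundary).any() and (grades < boundary).any():
            cuts.append(calibrate_threshold_roc(continuous_values, grades, boundary,
                                                direction=direction, criterion=criterion))
    if not cuts:
        raise CalibrationError(f"{site}: no attainable grade boundary in the reference")
    # successive boundaries must be strictly ordered; when overlapping classes
    # produce ties, nudge by a negligible epsilon so the grade map stays valid
    ordered = []
    for c in cuts:  # boundary order: higher grade => more extreme cutpoint
        if ordered:
            eps = 1e-9 * max(1.0, abs(c))
            c = max(c, ordered[-1] + eps) if direction == "greater" else min(c, ordered[-1] - eps)
        ordered.append(c)
    if direction == "less":
        ordered = sorted(ordered)
    return GradeThresholds(site=site, cutpoints=tuple(ordered), direction=direction)


def grade_from_thresholds(value, thresholds: GradeThresholds):
    """Ordinal grade for a value (scalar or array) under the given cutpoints."""
    v = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite measure value")
    cuts = np.asarray(thresholds.cutpoints)
    if thresholds.direction == "greater":
        g = (v[..., None] >= cuts).sum(axis=-1)
    else:
        g = (v[..., None] <= cuts).sum(axis=-1)
    return g if g.ndim else int(g)


# ---------------------------------------------------------------------------
# height adjustment of mJSW
# ---------------------------------------------------------------------------


def fit_height_adjustment(mjsw_mm: Sequence[float], height_cm: Sequence[float],
                          sex: Sequence[str]) -> HeightAdjustModel:
    """Per-sex linear regression of mJSW on height (complete-case)."""
    df = pd.DataFrame({"mjsw": mjsw_mm, "height": height_cm, "sex": sex}).dropna()
    slope, mean_h = {}, {}
    for s, grp in df.groupby("sex"):
        if len(grp) < 2 or grp["height"].nunique() < 2:
            raise ValueError(f"sex {s!r}: need >= 2 distinct heights to fit adjustment")
        b1, _ = np.polyfit(grp["height"], grp["mjsw"], 1)
        slope[s] = float(b1)
        mean_h[s] = float(grp["height"].mean())
    return HeightAdjustModel(slope=slope, mean_height=mean_h)


def height_adjust_mjsw(mjsw_mm, height_cm, sex, reference: HeightAdjustModel):
    """Residual-shift adjustment: adjusted = mjsw - slope_sex * (height - mean_height_sex).

    With slope 0 this is the identity.  Scalar or vector inputs; missing
    heights propagate NaN so callers can exclude (complete-case) and log.
    """
    mjsw = np.asarray(mjsw_mm, dtype=float)
    height = np.asarray(height_cm, dtype=float)
    sex_arr = np.asarray(sex)
    slopes = np.vectorize(lambda s: reference.slope[s])(sex_arr)
    means = np.vectorize(lambda s: reference.mean_height[s])(sex_arr)
    adjusted = mjsw - slopes * (height - means)
    return adjusted if adjusted.ndim else float(adjusted)


# ---------------------------------------------------------------------------
# binary classifications
# ---------------------------------------------------------------------------


def classify_morphology(alpha_angle_deg: float, lcea_deg: float,
                        cam_cut_deg: float = 60.0, pincer_cut_deg: float = 45.0,
                        ad_cut_deg: float = 25.0) -> Tuple[bool, bool, bool]:
    """(cam, pincer, acetabular_dysplasia) with inclusive bounds cam: AA>=60,
    pincer: LCEA>=45, AD: LCEA<25.  A NaN alpha angle (no departure found)
    yields cam=False; such records are classified on LCEA only.
    """
    cam = bool(np.isfinite(alpha_angle_deg) and alpha_angle_deg >= cam_cut_deg)
    pincer = bool(lcea_deg >= pincer_cut_deg)
    ad = bool(lcea_deg < ad_cut_deg)
    return cam, pincer, ad


def classify_rhoa(osteophyte_grades: Dict[str, int], jsn_grade: int) -> Tuple[bool, bool]:
    """(rhoa, rhoa_grade2): JSN >=1 with any-site osteophyte >=1; stricter variant at >=2 each."""
    worst = max(osteophyte_grades.values())
    rhoa = jsn_grade >= 1 and worst >= 1
    rhoa2 = jsn_grade >= 2 and worst >= 2
    return bool(rhoa), bool(rhoa2)


# ---------------------------------------------------------------------------
# cohort-level grading
# ---------------------------------------------------------------------------


def grade_cohort(df: pd.DataFrame,
                 osteophyte_thresholds: Dict[str, GradeThresholds],
                 jsn_thresholds: GradeThresholds,
                 height_model: HeightAdjustModel,
                 cam_cut_deg: float = 60.0, pincer_cut_deg: float = 45.0,
                 ad_cut_deg: float = 25.0) -> pd.DataFrame:
    """Apply the full grading stack to a measured cohort.

    Expects columns ``participant_id, alpha_angle_deg, lcea_deg, mjsw_mm,
    height_cm, sex`` and ``area_{site}_mm2`` for each osteophyte site.
    Returns one row per participant with grades, rHOA and morphology flags;
    rows with missing height are excluded (complete-case) by the caller
    using the returned NaN-adjusted values.
    """
    out = df[["participant_id"]].copy()
    adj = height_adjust_mjsw(df["mjsw_mm"], df["height_cm"], df["sex"], height_model)
    out["mjsw_adjusted_mm"] = adj
    out["jsn_grade"] = grade_from_thresholds(np.asarray(adj), jsn_thresholds)
    for site in OSTEOPHYTE_SITES:
        out[f"grade_{site}"] = grade_from_thresholds(
            df[f"area_{site}_mm2"].to_numpy(), osteophyte_thresholds[site])
    grades = out[[f"grade_{s}" for s in OSTEOPHYTE_SITES]].to_numpy()
    worst = grades.max(axis=1)
    out["rhoa"] = (out["jsn_grade"] >= 1) & (worst >= 1)
    out["rhoa_grade2"] = (out["jsn_grade"] >= 2) & (worst >= 2)
    morph = np.array([classify_morphology(a, l, cam_cut_deg, pincer_cut_deg, ad_cut_deg)
                      for a, l in zip(df["alpha_angle_deg"], df["lcea_deg"])])
    out["cam"], out["pincer"], out["acetabular_dysplasia"] = morph[:, 0].astype(bool), \
        morph[:, 1].astype(bool), morph[:, 2].astype(bool)
    out["alpha_undefined"] = ~np.isfinite(df["alpha_angle_deg"].to_numpy(dtype=float))
    return out
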