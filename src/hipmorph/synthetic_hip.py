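"""Synthetic hip cohorts with known ground truth.

Two generators make every pipeline stage testable without any imaging data:

* :func:`generate_hip_outline` builds one 85-point landmark outline whose
  geometric ground truth (alpha angle, LCEA, mJSW) is known exactly by
  construction — femoral-head points on a circle, an optional cam bump whose
  first tolerance crossing is analytically placed at the requested departure
  angle, an acetabular roof at a controllable centre-edge angle and
  joint-space gap, and a symmetric femoral neck about a known axis;
* :func:`generate_cohort` draws a participant cohort (covariates, morphology,
  per-site osteophyte presence/areas, JSN and hip pain from logistic /
  ordinal / gamma models with user-set odds ratios) and optionally renders
  each participant's landmarks from their latent geometry.

Default prevalences and effect sizes echo the published study population
(e.g. male cam prevalence 15.4%, male cam -> inferior femoral osteophyte OR
4.75); they are configuration, not data.  The 85-point template layout is
this package's own — only the index ranges consumed by the measurements
(15-28, 22-31, 78-84, edge 78) are anatomically constrained.

All randomness flows through one ``numpy.random.Generator``; identical seeds
and parameters give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hipgeom import N_LANDMARKS, HipMeasures, LandmarkSet, LandmarkTemplate

__all__ = [
    "ParameterError",
    "ShapeParams",
    "OutcomeModelParams",
    "generate_hip_outline",
    "generate_outcomes",
    "generate_cohort",
    "DEFAULT_TEMPLATE",
]

DEFAULT_TEMPLATE = LandmarkTemplate()

# outline angular layout (degrees, mathematical convention: CCW from +x;
# canonical frame has superior = +y, lateral = -x).  The head-circle fit
# points span a wide arc (as on a real articular surface) so the fitted
# centre and radius are well conditioned; the fit grid includes the superior
# pole (90 deg) exactly, where the mJSW minimum is attained.
_PHI_MEDIAL = (-178.0, -146.0)  # indices 1-14, inferomedial filler
_PHI_FIT = (-140.0, 102.0)      # indices 15-28 (head-circle fit range; one vertex pinned at 90)
_PHI_JUNCTION = (108.0, 203.0)  # indices 29-40 (departure scan range)
_BUMP_RISE_DEG = 20.0           # smoothstep rise width of the cam bump
_ROOF_MEDIAL_X = 2.0            # medial end of the flat acetabular roof (mm)


class ParameterError(ValueError):
    """Raised for shape or outcome-model parameters outside their valid domain."""


@dataclass(frozen=True)
class ShapeParams:
    """Geometric ground truth for one synthetic hip (mm, degrees)."""

    head_radius_mm: float = 25.0
    head_centre: Tuple[float, float] = (0.0, 0.0)
    neck_axis_angle_deg: float = 45.0   # inclination of the neck axis below the image x-axis
    cam_present: bool = False
    cam_departure_deg: float = 72.5     # ground-truth alpha angle when cam present
    cam_amplitude_frac: float = 0.10    # peak bump excess as a fraction of the head radius
    edge_angle_deg: float = 35.0        # ground-truth LCEA
    joint_space_mm: float = 4.0         # ground-truth mJSW
    landmark_noise_sd_mm: float = 0.0
    departure_tolerance_frac: float = 0.02

    def validate(self) -> None:
        if self.head_radius_mm <= 0:
            raise ParameterError("head_radius_mm must be > 0")
        if self.joint_space_mm <= 0:
            raise ParameterError("joint_space_mm must be > 0")
        if self.landmark_noise_sd_mm < 0:
            raise ParameterError("landmark_noise_sd_mm must be >= 0")
        if not 0.0 < self.cam_departure_deg < 180.0:
            raise ParameterError("cam_departure_deg must be in (0, 180)")
        if not 3.0 < self.edge_angle_deg < 80.0:
            raise ParameterError("edge_angle_deg must be in (3, 80)")
        if self.cam_present and self.cam_amplitude_frac <= self.departure_tolerance_frac:
            raise ParameterError("cam_amplitude_frac must exceed departure_tolerance_frac")


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def generate_hip_outline(params: ShapeParams,
                         template: LandmarkTemplate = DEFAULT_TEMPLATE,
                         rng: Optional[np.random.Generator] = None,
                         ) -> Tuple[LandmarkSet, HipMeasures]:
    """One synthetic 85-point outline plus its exact ground-truth measures.

    Head points (indices 1-40) lie on the head circle; with a cam the radial
    excess rises as a smoothstep whose crossing of ``radius * (1 + tol)`` is
    analytically placed at ``cam_departure_deg`` from the neck axis, so the
    ground-truth alpha angle is exact by construction.  The mJSW-bearing
    acetabular points (78-84) lie on the tangent line to the joint-space
    offset circle at the superior pole, which makes the minimum polyline
    distance equal ``joint_space_mm`` exactly; the lateral edge (point 78)
    sits on that line at ``edge_angle_deg`` from the vertical.  The neck is
    symmetric about the configured axis with its waist midpoint on the axis.
    """
    params.validate()
    r = params.head_radius_mm
    c = np.asarray(params.head_centre, dtype=float)
    theta_pos = 180.0 + params.neck_axis_angle_deg  # direction head -> neck, deg from +x
    u = np.array([math.cos(math.radians(theta_pos)), math.sin(math.radians(theta_pos))])
    nvec = np.array([-u[1], u[0]])  # inferomedial side of the neck axis

    phi = np.empty(40)
    phi[0:14] = np.linspace(*_PHI_MEDIAL, 14)
    phi[14:28] = np.linspace(*_PHI_FIT, 14)
    phi[26] = 90.0  # pin a fit vertex at the superior pole (mJSW foot point)
    phi[28:40] = np.linspace(*_PHI_JUNCTION, 12)

    excess = np.zeros(40)
    if params.cam_present:
        phi_dep = theta_pos - params.cam_departure_deg
        if not _PHI_FIT[1] + 3.0 <= phi_dep <= _PHI_JUNCTION[1] - 3.0:
            raise ParameterError(
                f"cam_departure_deg={params.cam_departure_deg} places the departure at "
                f"{phi_dep:.1f} deg, outside the generated junction arc")
        amp = params.cam_amplitude_frac * r
        q = params.departure_tolerance_frac / params.cam_amplitude_frac
        x_star = brentq(lambda x: x * x * (3.0 - 2.0 * x) - q, 0.0, 1.0, xtol=1e-14)
        phi0 = phi_dep - x_star * _BUMP_RISE_DEG
        excess = amp * _smoothstep((phi - phi0) / _BUMP_RISE_DEG)

    rad = np.radians(phi)
    pts = np.empty((N_LANDMARKS, 2))
    pts[0:40] = c + (r + excess)[:, None] * np.column_stack([np.cos(rad), np.sin(rad)])

    # femoral neck: symmetric borders about the axis, quadratic waist
    t = np.linspace(0.8 * r, 1.7 * r, 12)
    w = 0.6 * r + (0.25 / r) * (t - 1.24 * r) ** 2
    sup = c + t[:, None] * u - w[:, None] * nvec
    inf = c + t[:, None] * u + w[:, None] * nvec
    pts[40:52] = sup            # indices 41-52, walking away from the head
    pts[52:64] = inf[::-1]      # indices 53-64, walking back toward the head

    # acetabulum: flat roof on the tangent line y = R at the superior pole
    R = r + params.joint_space_mm
    x78 = -R * math.tan(math.radians(params.edge_angle_deg))
    roof_x = np.linspace(x78 + 0.4, _ROOF_MEDIAL_X, 6)
    pts[77] = c + np.array([x78, R])                       # index 78, lateral edge
    pts[78:84] = c + np.column_stack([roof_x, np.full(6, R)])  # indices 79-84
    rim_phi = np.radians(np.linspace(92.0, 96.0 + params.edge_angle_deg + 12.0, 13))
    pts[64:77] = c + (R + 6.0) * np.column_stack([np.cos(rim_phi), np.sin(rim_phi)])
    pts[84] = c + np.array([_ROOF_MEDIAL_X + 1.5, R + 2.0])  # index 85, medial filler

    if params.landmark_noise_sd_mm > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        pts = pts + rng.normal(0.0, params.landmark_noise_sd_mm, pts.shape)

    truth = HipMeasures(
        alpha_angle_deg=params.cam_departure_deg if params.cam_present else float("nan"),
        lcea_deg=params.edge_angle_deg,
        mjsw_mm=params.joint_space_mm,
    )
    if params.cam_present:
        truth.departure_point = c + r * (1.0 + params.departure_tolerance_frac) * np.array(
            [math.cos(math.radians(phi_dep)), math.sin(math.radians(phi_dep))])
    return LandmarkSet(participant_id="synthetic", points=pts), truth


# ---------------------------------------------------------------------------
# outcome model
# ---------------------------------------------------------------------------

_SITES = ("acetabular", "superior_femoral", "inferior_femoral")


def _d(**kw) -> Dict:
    return dict(kw)


@dataclass
class OutcomeModelParams:
    """Population model for the outcome cohort.

    Defaults echo the published descriptive table and association estimates
    (cam prevalence 15.4%/1.8% male/female; male cam -> osteophyte ORs
    1.87/1.94/4.75 at the acetabular/superior/inferior sites; cam -> JSN OR
    1.53; pincer -> JSN OR 4.03; AD -> JSN OR 0.29); they are configurable
    defaults, not values estimated from data.
    """

    cam_prevalence: Dict[str, float] = field(default_factory=lambda: _d(male=0.154, female=0.018))
    pincer_prevalence: Dict[str, float] = field(default_factory=lambda: _d(male=0.089, female=0.081))
    ad_prevalence: Dict[str, float] = field(default_factory=lambda: _d(male=0.056, female=0.070))

    op_base_prevalence: Dict[str, Dict[str, float]] = field(default_factory=lambda: {
        "acetabular": _d(male=0.120, female=0.095),
        "superior_femoral": _d(male=0.070, female=0.038),
        "inferior_femoral": _d(male=0.030, female=0.012)})
    op_log_or_cam: Dict[str, float] = field(default_factory=lambda: {
        "acetabular": math.log(1.87), "superior_femoral": math.log(1.94),
        "inferior_femoral": math.log(4.75)})
    op_log_or_pincer: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(_SITES, 0.0))
    op_log_or_ad: Dict[str, float] = field(default_factory=lambda: dict.fromkeys(_SITES, 0.0))
    op_grade_probs: Tuple[float, float, float] = (0.70, 0.25, 0.05)  # grade 1/2/3 given presence
    area_gamma_shape: float = 4.0
    area_gamma_scale: Dict[int, float] = field(default_factory=lambda: {1: 0.5, 2: 1.5, 3: 3.5})

    jsn_base_p: Dict[str, Tuple[float, float, float]] = field(default_factory=lambda: _d(
        male=(0.20, 0.045, 0.010), female=(0.13, 0.025, 0.005)))  # P(grade >= 1,2,3) at baseline
    jsn_log_or_cam: float = math.log(1.53)
    jsn_log_or_pincer: float = math.log(4.03)
    jsn_log_or_ad: float = math.log(0.29)
    jsn_cutpoints: Tuple[float, float, float] = (1.5, 2.0, 2.5)  # adjusted mJSW (mm)
    mjsw_height_slope: float = 0.012  # mm of mJSW per cm of height

    pain_base_prevalence: Dict[str, float] = field(default_factory=lambda: _d(male=0.050, female=0.095))
    pain_log_or_cam_direct: float = math.log(1.15)
    pain_log_or_op: Dict[str, float] = field(default_factory=lambda: {
        "acetabular": math.log(1.5), "superior_femoral": math.log(1.5),
        "inferior_femoral": math.log(2.2)})

    age_mean: Dict[str, float] = field(default_factory=lambda: _d(male=63.4, female=62.1))
    age_sd: float = 7.5
    age_range: Dict[str, Tuple[float, float]] = field(default_factory=lambda: _d(
        male=(45.0, 80.0), female=(46.0, 79.0)))
    height_mean: Dict[str, float] = field(default_factory=lambda: _d(male=177.0, female=163.3))
    height_sd: float = 6.8
    height_range: Dict[str, Tuple[float, float]] = field(default_factory=lambda: _d(
        male=(153.0, 203.0), female=(137.0, 195.0)))
    weight_mean: Dict[str, float] = field(default_factory=lambda: _d(male=83.8, female=68.7))
    weight_sd: float = 13.5
    weight_range: Dict[str, Tuple[float, float]] = field(default_factory=lambda: _d(
        male=(50.0, 160.0), female=(36.0, 155.0)))
    ethnicity_probs: Dict[str, float] = field(default_factory=lambda: {
        "White": 0.9694, "Asian": 0.0109, "Black": 0.0063, "Mixed": 0.0050,
        "Chinese": 0.0021, "Unknown": 0.0063})

    def validate(self) -> None:
        for name in ("cam_prevalence", "pincer_prevalence", "ad_prevalence",
                     "pain_base_prevalence"):
            for s, p in getattr(self, name).items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(f"{name}[{s}]={p} outside [0, 1]")
        for s in ("male", "female"):
            if self.pincer_prevalence[s] + self.ad_prevalence[s] > 1.0:
                raise ParameterError("pincer + AD prevalence exceeds 1 (mutually exclusive classes)")
            p1, p2, p3 = self.jsn_base_p[s]
            if not (1.0 > p1 >= p2 >= p3 > 0.0):
                raise ParameterError("jsn_base_p must be decreasing within (0, 1)")


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _trunc_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    return np.clip(out, lo, hi)


def generate_outcomes(n: int, params: Optional[OutcomeModelParams] = None,
                      rng: Optional[np.random.Generator] = None,
                      seed: Optional[int] = None) -> pd.DataFrame:
    """Outcome cohort (no geometry): covariates, morphology flags, osteophyte
    presence/grades/areas, JSN grade, latent adjusted/raw mJSW and hip pain.

    Generation order is morphology -> osteophytes/JSN -> pain, so osteophyte
    indicators sit on the causal path from cam to pain and adjustment-based
    attenuation is testable.
    """
    params = params or OutcomeModelParams()
    params.validate()
    if rng is None:
        rng = np.random.default_rng(0 if seed is None else seed)
    if n < 0:
        raise ParameterError("n must be >= 0")

    sex = np.where(np.arange(n) % 2 == 0, "male", "female")  # equal numbers by design
    male = sex == "male"
    df = pd.DataFrame({"participant_id": [f"P{i:06d}" for i in range(n)], "sex": sex})

    def per_sex(fn_male, fn_female):
        out = np.empty(n)
        out[male] = fn_male(int(male.sum()))
        out[~male] = fn_female(int((~male).sum()))
        return out

    df["age_years"] = per_sex(
        lambda k: _trunc_normal(rng, params.age_mean["male"], params.age_sd, *params.age_range["male"], k),
        lambda k: _trunc_normal(rng, params.age_mean["female"], params.age_sd, *params.age_range["female"], k))
    df["height_cm"] = per_sex(
        lambda k: _trunc_normal(rng, params.height_mean["male"], params.height_sd, *params.height_range["male"], k),
        lambda k: _trunc_normal(rng, params.height_mean["female"], params.height_sd, *params.height_range["female"], k))
    df["weight_kg"] = per_sex(
        lambda k: _trunc_normal(rng, params.weight_mean["male"], params.weight_sd, *params.weight_range["male"], k),
        lambda k: _trunc_normal(rng, params.weight_mean["female"], params.weight_sd, *params.weight_range["female"], k))
    eth_levels = list(params.ethnicity_probs)
    eth_p = np.array([params.ethnicity_probs[k] for k in eth_levels], dtype=float)
    eth_p = eth_p / eth_p.sum()
    df["ethnicity"] = rng.choice(eth_levels, size=n, p=eth_p) if n else np.array([], dtype=object)

    # morphology: cam independent; pincer/AD mutually exclusive LCEA classes
    p_cam = np.where(male, params.cam_prevalence["male"], params.cam_prevalence["female"])
    cam = rng.random(n) < p_cam
    p_pincer = np.where(male, params.pincer_prevalence["male"], params.pincer_prevalence["female"])
    p_ad = np.where(male, params.ad_prevalence["male"], params.ad_prevalence["female"])
    u_cov = rng.random(n)
    pincer = u_cov < p_pincer
    ad = (~pincer) & (u_cov < p_pincer + p_ad)
    df["cam"], df["pincer"], df["acetabular_dysplasia"] = cam.astype(int), pincer.astype(int), ad.astype(int)

    # latent continuous angles consistent with the flags
    aa = np.where(cam,
                  _trunc_normal(rng, 68.0, 6.0, 60.0, 100.0, n),
                  per_sex(lambda k: _trunc_normal(rng, 51.0, 4.5, 36.0, 59.9, k),
                          lambda k: _trunc_normal(rng, 44.5, 4.0, 34.0, 59.9, k)))
    lcea = np.where(pincer, _trunc_normal(rng, 48.0, 2.5, 45.0, 61.8, n),
                    np.where(ad, _trunc_normal(rng, 21.0, 3.0, 8.0, 24.9, n),
                             _trunc_normal(rng, 35.4, 4.5, 25.0, 44.9, n)))
    df["true_alpha_deg"], df["true_lcea_deg"] = aa, lcea

    # osteophytes: presence by logistic model, grade given presence, area given grade
    grade_cum = np.cumsum(params.op_grade_probs) / sum(params.op_grade_probs)
    for site in _SITES:
        base = np.where(male, params.op_base_prevalence[site]["male"],
                        params.op_base_prevalence[site]["female"])
        eta = (np.vectorize(_logit)(base) if n else np.array([])) \
            + params.op_log_or_cam[site] * cam \
            + params.op_log_or_pincer[site] * pincer + params.op_log_or_ad[site] * ad
        present = rng.random(n) < 1.0 / (1.0 + np.exp(-eta)) if n else np.array([], dtype=bool)
        grade = np.zeros(n, dtype=int)
        if n:
            g_u = rng.random(n)
            grade[present] = 1 + np.searchsorted(grade_cum[:-1], g_u[present], side="right")
        area = np.zeros(n)
        for g, scale in params.area_gamma_scale.items():
            m = grade == g
            if m.any():
                area[m] = rng.gamma(params.area_gamma_shape, scale, int(m.sum()))
        df[f"true_grade_{site}"] = grade
        df[f"area_{site}_mm2"] = area

    # JSN: cumulative-logit ordinal model, then an adjusted-mJSW value in the
    # grade's band and a raw value carrying the height relation
    theta = {s: tuple(_logit(p) for p in params.jsn_base_p[s]) for s in ("male", "female")}
    eta_jsn = (params.jsn_log_or_cam * cam + params.jsn_log_or_pincer * pincer
               + params.jsn_log_or_ad * ad)
    th = np.stack([[theta["male" if m else "female"][g] for g in range(3)] for m in male]) \
        if n else np.empty((0, 3))
    p_ge = 1.0 / (1.0 + np.exp(-(th + eta_jsn[:, None])))  # P(grade >= 1,2,3)
    u_j = rng.random(n)
    jsn_grade = (u_j[:, None] < p_ge).sum(axis=1)
    df["true_jsn_grade"] = jsn_grade
    cuts = params.jsn_cutpoints
    bands = {0: (cuts[2], 5.0), 1: (cuts[1], cuts[2]), 2: (cuts[0], cuts[1]), 3: (0.6, cuts[0])}
    adj = np.empty(n)
    for g, (lo, hi) in bands.items():
        m = jsn_grade == g
        if m.any():
            adj[m] = rng.uniform(lo + 1e-6, hi, int(m.sum()))
    mean_h = np.where(male, params.height_mean["male"], params.height_mean["female"])
    raw = adj + params.mjsw_height_slope * (df["height_cm"].to_numpy() - mean_h)
    df["true_mjsw_adjusted_mm"] = adj
    df["true_mjsw_raw_mm"] = np.clip(raw, 0.4, None)

    worst = df[[f"true_grade_{s}" for s in _SITES]].to_numpy().max(axis=1) if n else np.array([])
    df["true_rhoa"] = ((jsn_grade >= 1) & (worst >= 1)).astype(int)
    df["true_rhoa_grade2"] = ((jsn_grade >= 2) & (worst >= 2)).astype(int)

    # hip pain: direct cam effect plus per-site osteophyte effects
    base_pain = np.where(male, params.pain_base_prevalence["male"], params.pain_base_prevalence["female"])
    eta_pain = (np.vectorize(_logit)(base_pain) if n else np.array([])) \
        + params.pain_log_or_cam_direct * cam
    for site in _SITES:
        eta_pain = eta_pain + params.pain_log_or_op[site] * (df[f"true_grade_{site}"].to_numpy() >= 1)
    df["hip_pain"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta_pain))).astype(int) \
        if n else np.array([], dtype=int)
    return df


def generate_cohort(n: int, outcome_params: Optional[OutcomeModelParams] = None,
                    shape_defaults: Optional[ShapeParams] = None,
                    seed: int = 0, with_landmarks: bool = True,
                    template: LandmarkTemplate = DEFAULT_TEMPLATE,
                    ) -> Tuple[Optional[List[LandmarkSet]], pd.DataFrame]:
    """Full synthetic cohort: participants table plus (optionally) landmarks.

    Each participant's latent alpha angle, LCEA and raw mJSW are rendered
    into an 85-point outline via :func:`generate_hip_outline`; the table
    keeps the latent truths (``true_*`` columns) for recovery tests.
    """
    rng = np.random.default_rng(seed)
    df = generate_outcomes(n, outcome_params, rng=rng)
    shape = shape_defaults or ShapeParams(landmark_noise_sd_mm=0.3)
    landmarks: Optional[List[LandmarkSet]] = None
    if with_landmarks:
        landmarks = []
        male = (df["sex"] == "male").to_numpy()
        radii = np.where(male, rng.normal(26.0, 1.2, n), rng.normal(23.5, 1.1, n))
        radii = np.clip(radii, 18.0, 32.0)
        neck_angles = np.clip(rng.normal(shape.neck_axis_angle_deg, 2.5, n),
                              shape.neck_axis_angle_deg - 5.0, shape.neck_axis_angle_deg + 5.0)
        for i in range(n):
            p = replace(shape,
                        head_radius_mm=float(radii[i]),
                        neck_axis_angle_deg=float(neck_angles[i]),
                        cam_present=True,
                        cam_departure_deg=float(df["true_alpha_deg"].iloc[i]),
                        edge_angle_deg=float(df["true_lcea_deg"].iloc[i]),
                        joint_space_mm=float(df["true_mjsw_raw_mm"].iloc[i]))
            ls, _ = generate_hip_outline(p, template=template, rng=rng)
            ls.participant_id = df["participant_id"].iloc[i]
            landmarks.append(ls)
    return landmarks, df
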