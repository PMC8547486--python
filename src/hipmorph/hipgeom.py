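"""Landmark-based hip geometry.

Turns an ordered 85-point outline of the left proximal femur and acetabulum
(millimetre coordinates, canonical orientation: superior = +y, lateral = -x)
into the three scalar measures used for radiographic hip-OA phenotyping:

* alpha angle (AA) — angle at the femoral-head centre between the neck axis
  and the point where the head–neck contour first leaves the best-fit head
  circle; large values indicate cam morphology;
* lateral centre-edge angle (LCEA) — angle at the head centre between the
  vertical and the lateral acetabular edge (outline point 78); measures
  acetabular coverage;
* minimum joint-space width (mJSW) — smallest distance between the
  acetabular (points 78–84) and femoral (points 22–31) articular polylines.

Landmark indices are 1-based and index ranges are inclusive on both ends,
matching the "point 78" convention of the radiographic literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import isotonic_regression, least_squares

N_LANDMARKS = 85

__all__ = [
    "N_LANDMARKS",
    "DegenerateGeometryError",
    "ConfigurationError",
    "NoDepartureError",
    "LandmarkSet",
    "LandmarkTemplate",
    "CircleFit",
    "NeckAxis",
    "HipMeasures",
    "fit_circle",
    "estimate_neck_axis",
    "compute_alpha_angle",
    "compute_lcea",
    "compute_mjsw",
    "polyline_min_distance",
    "measure_hip",
    "read_landmarks_csv",
    "write_landmarks_csv",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric construction is ill-posed (collinear points, zero-length segment...)."""


class ConfigurationError(ValueError):
    """Raised when template index ranges are invalid or degenerate."""


class NoDepartureError(RuntimeError):
    """Raised when the scanned contour never leaves the fitted head circle (AA undefined)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

IndexRange = Tuple[int, int]  # 1-based, inclusive on both ends


def _check_range(rng: IndexRange, name: str) -> None:
    lo, hi = rng
    if not (1 <= lo <= hi <= N_LANDMARKS):
        raise ConfigurationError(f"{name} {rng} not a non-empty range within [1, {N_LANDMARKS}]")


@dataclass(frozen=True)
class LandmarkTemplate:
    """Index ranges mapping outline positions to anatomy.

    Defaults follow the published template usage: head circle fit on points
    15–28, mJSW between acetabular points 78–84 and femoral points 22–31,
    lateral acetabular edge at point 78. The neck ranges are this package's
    own convention (the full template anatomy is not published) and are
    configurable.
    """

    head_circle_range: IndexRange = (15, 28)
    mjsw_acetabulum_range: IndexRange = (78, 84)
    mjsw_femoral_range: IndexRange = (22, 31)
    lateral_edge_index: int = 78
    neck_superior_range: IndexRange = (41, 52)
    neck_inferior_range: IndexRange = (53, 64)

    def __post_init__(self) -> None:
        for name in ("head_circle_range", "mjsw_acetabulum_range", "mjsw_femoral_range",
                     "neck_superior_range", "neck_inferior_range"):
            _check_range(getattr(self, name), name)
        if not 1 <= self.lateral_edge_index <= N_LANDMARKS:
            raise ConfigurationError(f"lateral_edge_index {self.lateral_edge_index} outside [1, {N_LANDMARKS}]")

    def slice(self, rng: IndexRange) -> slice:
        """0-based slice selecting a 1-based inclusive index range."""
        return slice(rng[0] - 1, rng[1])


@dataclass
class LandmarkSet:
    """Ordered 85-point outline of one left hip, canonical orientation."""

    participant_id: str
    points: np.ndarray  # (85, 2) float, mm
    side: str = "left"
    orientation: str = "canonical"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(f"expected ({N_LANDMARKS}, 2) points, got {self.points.shape}")

    def validate(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.participant_id}: non-finite coordinates")
        steps = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(steps == 0.0):
            raise ValueError(f"{self.participant_id}: coincident consecutive outline points")

    def get(self, rng: IndexRange) -> np.ndarray:
        return self.points[rng[0] - 1 : rng[1]]


@dataclass(frozen=True)
class CircleFit:
    centre: np.ndarray  # (2,)
    radius: float
    rms_radial_residual: float
    n_points: int


@dataclass(frozen=True)
class NeckAxis:
    head_centre: np.ndarray
    neck_centre: np.ndarray
    direction: np.ndarray  # unit vector, head -> neck


@dataclass
class HipMeasures:
    """Per-hip scalar measures; alpha_angle_deg is NaN when no departure was found."""

    participant_id: str = ""
    alpha_angle_deg: float = float("nan")
    lcea_deg: float = float("nan")
    mjsw_mm: float = float("nan")
    departure_point: Optional[np.ndarray] = None

    @property
    def departure_flag(self) -> bool:
        """True when the contour never left the head circle (AA undefined)."""
        return not np.isfinite(self.alpha_angle_deg)


# ---------------------------------------------------------------------------
# circle of best fit
# ---------------------------------------------------------------------------


def _kasa_centre(pts: np.ndarray) -> np.ndarray:
    # algebraic (Kasa) fit: linear least squares on x^2+y^2 = a x + b y + c
    A = np.column_stack([pts, np.ones(len(pts))])
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:2] / 2.0


def fit_circle(points: Sequence[Sequence[float]]) -> CircleFit:
    """Geometric least-squares circle: minimises sum((||p_i - c|| - r)^2).

    An algebraic fit provides the initial centre, refined by Gauss–Newton on
    the geometric radial residuals (with the radius profiled out as the mean
    distance to the centre).  The solution is invariant to point order and
    equivariant under rigid motions.

    Raises
    ------
    DegenerateGeometryError
        For fewer than 3 points or a collinear configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError("circle fit needs at least 3 planar points")
    if not np.all(np.isfinite(pts)):
        raise DegenerateGeometryError("non-finite coordinates")
    centred = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centred, compute_uv=False)
    if sv[0] == 0.0 or sv[-1] / sv[0] < 1e-9:
        raise DegenerateGeometryError("points are (near-)collinear; circle undefined")

    def residuals(c: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(pts - c, axis=1)
        return d - d.mean()

    c0 = _kasa_centre(pts)
    sol = least_squares(residuals, c0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    centre = sol.x
    d = np.linalg.norm(pts - centre, axis=1)
    radius = float(d.mean())
    rms = float(np.sqrt(np.mean((d - radius) ** 2)))
    return CircleFit(centre=centre, radius=radius, rms_radial_residual=rms, n_points=len(pts))


# ---------------------------------------------------------------------------
# neck axis
# ---------------------------------------------------------------------------


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> Tuple[float, np.ndarray]:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a)), a
    t = float(np.clip((p - a) @ ab / denom, 0.0, 1.0))
    q = a + t * ab
    return float(np.linalg.norm(p - q)), q


def _closest_pair_to_polyline(P: np.ndarray, Q: np.ndarray) -> Tuple[float, np.ndarray, np.ndarray]:
    """Closest (vertex of P) -> (point on polyline Q) pair."""
    best = (np.inf, P[0], Q[0])
    for p in P:
        for i in range(len(Q) - 1):
            d, q = _point_segment_distance(p, Q[i], Q[i + 1])
            if d < best[0]:
                best = (d, p, q)
    return best


def estimate_neck_axis(landmarks: LandmarkSet, template: LandmarkTemplate,
                       circle: CircleFit) -> NeckAxis:
    """Neck axis through the fitted head centre and the femoral-neck centre.

    The neck centre is the midpoint of the minimum-width cross-section
    between the superior and inferior neck border polylines — the narrowest
    point of the neck waist.  This construction is a documented stand-in: it
    is configurable via the template's neck index ranges.
    """
    sup_rng, inf_rng = template.neck_superior_range, template.neck_inferior_range
    if sup_rng == inf_rng:
        raise ConfigurationError("neck superior and inferior ranges are identical")
    if max(sup_rng[0], inf_rng[0]) <= min(sup_rng[1], inf_rng[1]):
        raise ConfigurationError("neck ranges overlap")
    hc = template.head_circle_range
    for rng, name in ((sup_rng, "neck_superior_range"), (inf_rng, "neck_inferior_range")):
        if max(rng[0], hc[0]) <= min(rng[1], hc[1]):
            raise ConfigurationError(f"{name} overlaps head_circle_range")
        if rng[1] - rng[0] < 1:
            raise ConfigurationError(f"{name} must contain at least 2 points")
    sup = landmarks.get(sup_rng)
    inf = landmarks.get(inf_rng)
    cand = [_closest_pair_to_polyline(sup, inf), _closest_pair_to_polyline(inf, sup)]
    width, p, q = min(cand, key=lambda t: t[0])
    if width == 0.0:
        raise ConfigurationError("zero-width neck cross-section")
    neck_centre = (p + q) / 2.0
    vec = neck_centre - circle.centre
    norm = np.linalg.norm(vec)
    if norm == 0.0:
        raise DegenerateGeometryError("neck centre coincides with head centre")
    return NeckAxis(head_centre=circle.centre.copy(), neck_centre=neck_centre,
                    direction=vec / norm)


# ---------------------------------------------------------------------------
# alpha angle
# ---------------------------------------------------------------------------


def _angle_between_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def compute_alpha_angle(landmarks: LandmarkSet, template: LandmarkTemplate,
                        circle: CircleFit, axis: NeckAxis,
                        departure_tolerance_frac: float = 0.02) -> HipMeasures:
    """Alpha angle from the first departure of the head–neck contour.

    Walks the outline from the last head-circle index toward the neck (along
    increasing index, up to the start of the superior neck range) and finds
    the first location where the radial distance from the fitted centre
    exceeds ``radius * (1 + departure_tolerance_frac)``.  The crossing is
    linearly interpolated between the last interior and first exterior
    outline points; AA is the angle at the head centre between the neck-axis
    direction and the direction to the crossing point.

    Raises
    ------
    NoDepartureError
        When no scanned point exceeds the tolerance (spherical head).
    """
    if not 0.0 < departure_tolerance_frac < 0.2:
        raise ConfigurationError("departure_tolerance_frac must be in (0, 0.2)")
    start = template.head_circle_range[1]
    stop = template.neck_superior_range[0] - 1
    if stop <= start:
        raise ConfigurationError("no outline indices between head circle and superior neck")
    scan = landmarks.points[start - 1 : stop]
    c = circle.centre
    radial = np.linalg.norm(scan - c, axis=1)
    # The radial excess over the head circle grows monotonically along the
    # head-neck junction, which licenses two denoising steps that are exact
    # identities on a noiseless (monotone) profile: a median-of-3 prefilter
    # against isolated landmark-noise spikes, then an isotonic fit that pools
    # the pre-departure plateau.  The threshold is anchored on the larger of
    # the fitted radius and the plateau's own median (iterated), because the
    # circle extrapolated beyond the fit arc carries more radial error than
    # the plateau itself.
    profile = radial.copy()
    if len(profile) >= 3:
        profile[1:-1] = np.median(np.stack([radial[:-2], radial[1:-1], radial[2:]]), axis=0)
        profile[0] = min(radial[0], radial[1])
        profile = isotonic_regression(profile).x
    base = circle.radius
    j = None
    for _ in range(4):
        threshold = base * (1.0 + departure_tolerance_frac)
        outside = profile > threshold
        if not outside.any():
            raise NoDepartureError("contour never leaves the fitted circle within the scan range")
        j = int(np.argmax(outside))  # first exterior point
        if j >= 2:
            anchored = max(circle.radius, float(np.median(radial[:j])))
            if anchored > base + 1e-12:
                base = anchored
                continue
        break
    if j == 0:
        crossing = scan[0]
    else:
        r0, r1 = profile[j - 1], profile[j]
        t = 0.5 if r1 == r0 else float(np.clip((threshold - r0) / (r1 - r0), 0.0, 1.0))
        crossing = scan[j - 1] + t * (scan[j] - scan[j - 1])
    alpha = _angle_between_deg(axis.direction, crossing - c)
    return HipMeasures(participant_id=landmarks.participant_id,
                       alpha_angle_deg=alpha, departure_point=crossing)


# ---------------------------------------------------------------------------
# lateral centre-edge angle
# ---------------------------------------------------------------------------


def compute_lcea(landmarks: LandmarkSet, template: LandmarkTemplate,
                 circle: CircleFit) -> HipMeasures:
    """Signed LCEA at the head centre between the vertical and the lateral edge.

    Positive when the acetabular edge (default outline point 78) lies lateral
    of the vertical through the head centre (-x in the canonical frame),
    negative when medial (extreme dysplasia).
    """
    idx = template.lateral_edge_index
    edge = landmarks.points[idx - 1]
    v = edge - circle.centre
    if np.linalg.norm(v) == 0.0:
        raise DegenerateGeometryError("lateral edge point coincides with head centre")
    # angle from the +y (superior) vertical, positive toward -x (lateral)
    lcea = float(np.degrees(np.arctan2(-v[0], v[1])))
    return HipMeasures(participant_id=landmarks.participant_id, lcea_deg=lcea)


# ---------------------------------------------------------------------------
# minimum joint-space width
# ---------------------------------------------------------------------------


def polyline_min_distance(P: np.ndarray, Q: np.ndarray) -> float:
    """Minimum Euclidean distance between two polylines (vertex lists).

    Computed as the minimum over all point-to-segment distances in both
    directions, which equals the true polyline distance for non-crossing
    polylines; symmetric in its arguments.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)

    def one_way(A: np.ndarray, B: np.ndarray) -> float:
        a, b = B[:-1], B[1:]  # (m, 2) segment ends
        ab = b - a
        denom = (ab ** 2).sum(axis=1)  # (m,)
        ap = A[:, None, :] - a[None, :, :]  # (n, m, 2)
        t = np.einsum("nmk,mk->nm", ap, ab)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, t / denom, 0.0)
        t = np.clip(t, 0.0, 1.0)
        q = a[None, :, :] + t[..., None] * ab[None, :, :]
        d = np.linalg.norm(A[:, None, :] - q, axis=2)
        return float(d.min())

    if len(P) < 2 or len(Q) < 2:
        raise ConfigurationError("each polyline needs at least 2 points")
    return min(one_way(P, Q), one_way(Q, P))


def compute_mjsw(landmarks: LandmarkSet, template: LandmarkTemplate) -> HipMeasures:
    """Superior minimum joint-space width between the acetabular and femoral polylines."""
    a_rng, f_rng = template.mjsw_acetabulum_range, template.mjsw_femoral_range
    if max(a_rng[0], f_rng[0]) <= min(a_rng[1], f_rng[1]):
        raise ConfigurationError("mJSW acetabular and femoral ranges overlap")
    acet = landmarks.get(a_rng)
    fem = landmarks.get(f_rng)
    return HipMeasures(participant_id=landmarks.participant_id,
                       mjsw_mm=polyline_min_distance(acet, fem))


# ---------------------------------------------------------------------------
# convenience: full per-hip measurement
# ---------------------------------------------------------------------------


def measure_hip(landmarks: LandmarkSet, template: Optional[LandmarkTemplate] = None,
                departure_tolerance_frac: float = 0.02) -> HipMeasures:
    """All three measures for one hip; AA set to NaN (flagged) when no departure exists."""
    template = template or LandmarkTemplate()
    landmarks.validate()
    circle = fit_circle(landmarks.get(template.head_circle_range))
    axis = estimate_neck_axis(landmarks, template, circle)
    out = HipMeasures(participant_id=landmarks.participant_id)
    try:
        aa = compute_alpha_angle(landmarks, template, circle, axis, departure_tolerance_frac)
        out.alpha_angle_deg = aa.alpha_angle_deg
        out.departure_point = aa.departure_point
    except NoDepartureError:
        pass
    out.lcea_deg = compute_lcea(landmarks, template, circle).lcea_deg
    out.mjsw_mm = compute_mjsw(landmarks, template).mjsw_mm
    return out


# ---------------------------------------------------------------------------
# landmark CSV I/O  (header: participant_id,point_index,x_mm,y_mm)
# ---------------------------------------------------------------------------


def read_landmarks_csv(path) -> list[LandmarkSet]:
    df = pd.read_csv(path, dtype={"participant_id": str})
    required = {"participant_id", "point_index", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise ValueError(f"landmark CSV must have columns {sorted(required)}")
    out = []
    for pid, grp in df.groupby("participant_id", sort=False):
        grp = grp.sort_values("point_index")
        if len(grp) != N_LANDMARKS or list(grp["point_index"]) != list(range(1, N_LANDMARKS + 1)):
            raise ValueError(f"{pid}: expected point_index 1..{N_LANDMARKS}, got {len(grp)} rows")
        out.append(LandmarkSet(participant_id=str(pid),
                               points=grp[["x_mm", "y_mm"]].to_numpy(dtype=float)))
    return out


def write_landmarks_csv(landmark_sets: Sequence[LandmarkSet], path) -> None:
    rows = []
    for ls in landmark_sets:
        rows.append(pd.DataFrame({
            "participant_id": ls.participant_id,
            "point_index": np.arange(1, N_LANDMARKS + 1),
            "x_mm": ls.points[:, 0],
            "y_mm": ls.points[:, 1],
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
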