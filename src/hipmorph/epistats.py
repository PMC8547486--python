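"""Association statistics, repeatability metrics and descriptive tables.

Logistic-regression layer relating hip morphology (cam, pincer, acetabular
dysplasia) to radiographic hip OA, per-site osteophytes, JSN and hip pain:
odds ratios with Wald 95% confidence intervals and two-sided Wald p-values,
sex-stratified and combined, unadjusted and adjusted for age, height, weight
and ethnicity (plus sex in combined models).  Also provides the restricted
LCEA-reference sensitivity analysis, the hip-pain osteophyte-attenuation
models, Cohen's kappa / percent agreement / Lin's concordance correlation
coefficient for repeatability, and the descriptive prevalence table.

Maximum-likelihood fits go through statsmodels (IRLS on a binomial GLM);
perfect separation is detected and flagged rather than silently reported,
with an optional Firth (Jeffreys-penalised) fallback behind a flag.
"""

from __future__ import annotations

import decimal
import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "AssociationResult",
    "AgreementResult",
    "AnalysisSkipped",
    "fit_logistic",
    "run_association_suite",
    "run_sensitivity_restricted_reference",
    "run_pain_attenuation",
    "cohens_kappa",
    "lin_ccc",
    "prevalence_table",
    "round_half_away",
    "results_to_frame",
    "EXPOSURES",
    "OUTCOMES",
    "ETHNICITY_LEVELS",
    "ADJUSTMENT_COVARIATES",
]

Z95 = float(norm.ppf(0.975))

EXPOSURES = ("cam", "pincer", "acetabular_dysplasia")
OUTCOMES = ("rhoa", "op_acetabular", "op_superior_femoral", "op_inferior_femoral",
            "jsn", "hip_pain")
ETHNICITY_LEVELS = ("White", "Asian", "Black", "Mixed", "Chinese", "Unknown")
ADJUSTMENT_COVARIATES = ("age_years", "height_cm", "weight_kg")  # + ethnicity dummies (+ sex)


class AnalysisSkipped(RuntimeError):
    """Raised when a model cell cannot be fitted (single-class outcome or exposure)."""


@dataclass
class AssociationResult:
    exposure: str
    outcome: str
    stratum: str = "combined"
    adjusted: bool = False
    odds_ratio: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    n_used: int = 0
    status: str = "ok"  # ok | separation | skipped
    note: str = ""


@dataclass
class AgreementResult:
    kappa: float = float("nan")
    percent_agreement: float = float("nan")
    ccc: float = float("nan")
    status: str = "ok"


def results_to_frame(results: Iterable[AssociationResult]) -> pd.DataFrame:
    """Long-format results table: exposure,outcome,stratum,adjusted,or,ci_low,ci_high,p,n_used,status."""
    return pd.DataFrame([{
        "exposure": r.exposure, "outcome": r.outcome, "stratum": r.stratum,
        "adjusted": r.adjusted, "or": r.odds_ratio, "ci_low": r.ci_low,
        "ci_high": r.ci_high, "p": r.p_value, "n_used": r.n_used,
        "status": r.status, "note": r.note,
    } for r in results])


# ---------------------------------------------------------------------------
# logistic fits
# ---------------------------------------------------------------------------


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                 tol: float = 1e-10) -> Tuple[np.ndarray, np.ndarray]:
    """Jeffreys-penalised logistic regression (Firth); returns (beta, se)."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        mu = expit(X @ beta)
        W = mu * (1.0 - mu)
        XtW = X.T * W
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * W
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    mu = expit(X @ beta)
    info = (X.T * (mu * (1 - mu))) @ X
    se = np.sqrt(np.diag(np.linalg.pinv(info)))
    return beta, se


def fit_logistic(outcome: Sequence, exposure: Sequence,
                 covariates: Optional[pd.DataFrame] = None,
                 exposure_name: str = "exposure", outcome_name: str = "outcome",
                 stratum: str = "combined", firth: bool = False) -> AssociationResult:
    """Odds ratio for a binary exposure from a maximum-likelihood logistic model.

    IRLS via a binomial GLM; OR = exp(coefficient on exposure), Wald 95% CI
    ``exp(coef +/- 1.96*SE)``, two-sided Wald p.  Complete-case: rows with any
    missing value are dropped before fitting.  Perfect separation produces a
    flagged result (``status="separation"``) unless ``firth=True``, in which
    case the Jeffreys-penalised estimate is reported and annotated.

    Raises
    ------
    AnalysisSkipped
        When outcome or exposure has a single class in the analysis sample.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), name="y")
    x = pd.Series(np.asarray(exposure, dtype=float), name="x")
    frames = [y, x] + ([covariates.reset_index(drop=True)] if covariates is not None else [])
    data = pd.concat([f.reset_index(drop=True) for f in frames], axis=1).dropna()
    n_used = len(data)
    adjusted = covariates is not None and covariates.shape[1] > 0
    if data["y"].nunique() < 2:
        raise AnalysisSkipped(f"{outcome_name}: single-class outcome (n={n_used})")
    if data["x"].nunique() < 2:
        raise AnalysisSkipped(f"{exposure_name}: single-class exposure (n={n_used})")
    X = sm.add_constant(data.drop(columns="y").to_numpy(dtype=float), prepend=True)
    yv = data["y"].to_numpy(dtype=float)

    res = AssociationResult(exposure=exposure_name, outcome=outcome_name,
                            stratum=stratum, adjusted=adjusted, n_used=n_used)
    try:
        with warnings.catch_warnings():
            # separation is detected below and reported as a flagged result
            warnings.simplefilter("ignore")
            model = sm.GLM(yv, X, family=sm.families.Binomial())
            fit = model.fit(maxiter=50, tol=1e-8)
        beta, se = fit.params, fit.bse
        separated = (not np.all(np.isfinite(se))) or np.abs(beta[1]) > 15 or se[1] > 50
    except Exception as exc:  # noqa: BLE001 - statsmodels raises several types here
        separated, beta, se = True, None, None
        res.note = type(exc).__name__
    if separated:
        if firth:
            beta, se = _firth_logit(X, yv)
            res.status = "ok"
            res.note = (res.note + "; " if res.note else "") + "firth"
        else:
            res.status = "separation"
            res.note = (res.note + "; " if res.note else "") + "perfect or quasi-separation"
            return res
    b, s = float(beta[1]), float(se[1])
    res.odds_ratio = float(np.exp(b))
    res.ci_low = float(np.exp(b - Z95 * s))
    res.ci_high = float(np.exp(b + Z95 * s))
    res.p_value = float(2.0 * norm.sf(abs(b) / s)) if s > 0 else float("nan")
    return res


# ---------------------------------------------------------------------------
# design-matrix helpers
# ---------------------------------------------------------------------------


def _adjustment_matrix(df: pd.DataFrame, include_sex: bool) -> pd.DataFrame:
    """age, height, weight, one-hot ethnicity (White reference) and optionally sex."""
    cov = df[list(ADJUSTMENT_COVARIATES)].astype(float).copy()
    eth = pd.Categorical(df["ethnicity"], categories=ETHNICITY_LEVELS)
    for level in ETHNICITY_LEVELS[1:]:  # White is the reference (97% of the sample)
        cov[f"eth_{level}"] = (eth == level).astype(float)
    if include_sex:
        cov["sex_male"] = (df["sex"] == "male").astype(float)
    return cov


def _strata(df: pd.DataFrame) -> Dict[str, pd.DataFrame]:
    return {"male": df[df["sex"] == "male"], "female": df[df["sex"] == "female"],
            "combined": df}


def _cell(df: pd.DataFrame, exposure: str, outcome: str, stratum: str,
          adjusted: bool, firth: bool = False) -> AssociationResult:
    cov = _adjustment_matrix(df, include_sex=(stratum == "combined")) if adjusted else None
    try:
        return fit_logistic(df[outcome].astype(float), df[exposure].astype(float),
                            covariates=cov, exposure_name=exposure,
                            outcome_name=outcome, stratum=stratum, firth=firth)
    except AnalysisSkipped as exc:
        return AssociationResult(exposure=exposure, outcome=outcome, stratum=stratum,
                                 adjusted=adjusted, n_used=len(df.dropna(subset=[exposure, outcome])),
                                 status="skipped", note=str(exc))


def _ensure_outcome_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Derive binary outcome columns from grades where not already present."""
    df = df.copy()
    if "jsn" not in df and "jsn_grade" in df:
        df["jsn"] = (df["jsn_grade"] >= 1).astype(int)
    for site in ("acetabular", "superior_femoral", "inferior_femoral"):
        col = f"op_{site}"
        if col not in df and f"grade_{site}" in df:
            df[col] = (df[f"grade_{site}"] >= 1).astype(int)
    for col in ("rhoa", "rhoa_grade2", "hip_pain", "cam", "pincer", "acetabular_dysplasia"):
        if col in df:
            df[col] = df[col].astype(float)
    return df


# ---------------------------------------------------------------------------
# the association suite
# ---------------------------------------------------------------------------


def run_association_suite(cohort: pd.DataFrame,
                          exposures: Sequence[str] = EXPOSURES,
                          outcomes: Sequence[str] = OUTCOMES,
                          strata: Sequence[str] = ("male", "female", "combined"),
                          firth: bool = False) -> List[AssociationResult]:
    """One result per exposure x outcome x stratum x {unadjusted, adjusted} cell.

    Skipped or separated cells are emitted as flagged results — the suite
    never aborts on a single failed cell, and no cell is silently omitted.
    """
    df = _ensure_outcome_columns(cohort)
    parts = _strata(df)
    out: List[AssociationResult] = []
    for exposure, outcome, stratum, adjusted in itertools.product(
            exposures, outcomes, strata, (False, True)):
        out.append(_cell(parts[stratum], exposure, outcome, stratum, adjusted, firth=firth))
    return out


def run_sensitivity_restricted_reference(cohort: pd.DataFrame,
                                         outcomes: Sequence[str] = OUTCOMES,
                                         strata: Sequence[str] = ("male", "female", "combined"),
                                         reference_low: float = 25.0,
                                         reference_high: float = 45.0,
                                         firth: bool = False) -> List[AssociationResult]:
    """Pincer and AD versus a restricted normal-coverage reference.

    Each morphology is compared against participants with LCEA in
    [reference_low, reference_high) only; rows carrying the other morphology
    are dropped from that model.
    """
    df = _ensure_outcome_columns(cohort)
    in_ref = (df["lcea_deg"] >= reference_low) & (df["lcea_deg"] < reference_high)
    out: List[AssociationResult] = []
    for exposure in ("pincer", "acetabular_dysplasia"):
        sub = df[(df[exposure] > 0) | in_ref]
        parts = _strata(sub)
        for outcome, stratum, adjusted in itertools.product(outcomes, strata, (False, True)):
            r = _cell(parts[stratum], exposure, outcome, stratum, adjusted, firth=firth)
            r.note = (r.note + "; " if r.note else "") + "restricted LCEA reference"
            out.append(r)
    return out


def run_pain_attenuation(cohort: pd.DataFrame, stratum: str = "male",
                         firth: bool = False) -> List[AssociationResult]:
    """Cam -> hip-pain models probing attenuation by osteophyte adjustment.

    Five adjusted models: demographic covariates alone, plus each per-site
    osteophyte-presence indicator in turn, plus all three combined.  A drop
    of the cam OR toward 1 after osteophyte adjustment indicates the
    association runs partly through osteophyte formation (not a formal
    mediation analysis).
    """
    df = _ensure_outcome_columns(cohort)
    df = _strata(df)[stratum]
    op_cols = ["op_acetabular", "op_superior_femoral", "op_inferior_femoral"]
    variants = [("demographics", []), ("+op_acetabular", op_cols[:1]),
                ("+op_superior_femoral", op_cols[1:2]),
                ("+op_inferior_femoral", op_cols[2:3]), ("+all_osteophytes", op_cols)]
    out: List[AssociationResult] = []
    for label, extra in variants:
        cov = _adjustment_matrix(df, include_sex=(stratum == "combined"))
        for col in extra:
            cov[col] = df[col].astype(float).to_numpy()
        try:
            r = fit_logistic(df["hip_pain"].astype(float), df["cam"].astype(float),
                             covariates=cov.reset_index(drop=True), exposure_name="cam",
                             outcome_name="hip_pain", stratum=stratum, firth=firth)
        except AnalysisSkipped as exc:
            r = AssociationResult(exposure="cam", outcome="hip_pain", stratum=stratum,
                                  adjusted=True, status="skipped", note=str(exc))
        r.note = (r.note + "; " if r.note else "") + label
        out.append(r)
    return out


# ---------------------------------------------------------------------------
# repeatability metrics
# ---------------------------------------------------------------------------


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> AgreementResult:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the product of marginal label
    distributions.  When both raters are constant and identical (p_e = 1)
    kappa is undefined and the result is flagged.
    """
    a = pd.Series(labels_a).reset_index(drop=True)
    b = pd.Series(labels_b).reset_index(drop=True)
    if len(a) != len(b) or len(a) == 0:
        raise ValueError("label vectors must be non-empty and the same length")
    p_o = float((a == b).mean())
    cats = pd.Index(sorted(set(a) | set(b)))
    pa = a.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    pb = b.value_counts(normalize=True).reindex(cats, fill_value=0.0)
    p_e = float((pa * pb).sum())
    if p_e >= 1.0:
        return AgreementResult(kappa=float("nan"), percent_agreement=100.0 * p_o,
                               status="undefined: both raters constant and identical")
    return AgreementResult(kappa=(p_o - p_e) / (1.0 - p_e), percent_agreement=100.0 * p_o)


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> AgreementResult:
    """Lin's concordance correlation coefficient with population (1/n) moments:

        CCC = 2 cov(x, y) / (var(x) + var(y) + (mean(x) - mean(y))^2)
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1 or len(xv) < 2:
        raise ValueError("need two equal-length vectors with >= 2 entries")
    vx, vy = xv.var(), yv.var()
    denom = vx + vy + (xv.mean() - yv.mean()) ** 2
    if denom == 0.0:
        return AgreementResult(ccc=float("nan"), status="undefined: both vectors constant")
    ccc = 2.0 * np.cov(xv, yv, bias=True)[0, 1] / denom
    return AgreementResult(ccc=float(ccc))


# ---------------------------------------------------------------------------
# descriptive (prevalence) table
# ---------------------------------------------------------------------------


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention used for reported tables).

    Works on the shortest decimal representation of ``x`` so that values
    like 1.85 round to 1.9 despite binary floating point.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


_BINARY_ROWS = ("cam", "pincer", "acetabular_dysplasia", "rhoa", "op_acetabular",
                "op_superior_femoral", "op_inferior_femoral", "jsn", "rhoa_grade2",
                "hip_pain")
_CONTINUOUS_ROWS = ("age_years", "height_cm", "weight_kg", "alpha_angle_deg", "lcea_deg")


def prevalence_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table per stratum: counts + percentages (1 dp, half away
    from zero) for binary phenotypes, mean and range for continuous measures.
    """
    if len(cohort) == 0:
        return pd.DataFrame(columns=["variable", "stratum", "n", "count", "percent",
                                     "mean", "min", "max"])
    df = _ensure_outcome_columns(cohort)
    rows = []
    for stratum, part in _strata(df).items():
        n = len(part)
        if n == 0:
            continue
        for var in _BINARY_ROWS:
            if var not in part:
                continue
            count = int(part[var].fillna(0).astype(float).sum())
            rows.append({"variable": var, "stratum": stratum, "n": n, "count": count,
                         "percent": round_half_away(100.0 * count / n, 1)})
        for var in _CONTINUOUS_ROWS:
            if var not in part:
                continue
            vals = part[var].dropna().astype(float)
            if len(vals) == 0:
                continue
            rows.append({"variable": var, "stratum": stratum, "n": n,
                         "mean": float(vals.mean()), "min": float(vals.min()),
                         "max": float(vals.max())})
    return pd.DataFrame(rows)
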