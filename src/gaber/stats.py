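"""Cohort-level statistics.

Covers the association layer around the border-expansion measurement:
the perimeter-adjusted growth rate, univariable linear mixed-effects
models of eye-level growth outcomes against baseline morphology (eyes
nested in patients via a random patient intercept), the zone-level
eccentricity mixed model (eye-level random intercept nested in a
patient-level random intercept and eccentricity slope), the Friedman
test across ETDRS quadrants, and the two segmentation-agreement
metrics (Dice and the two-way absolute-agreement single-measurement
ICC).

Mixed-model estimation is delegated to statsmodels ``MixedLM``
(REML); everything upstream — the construction of outcomes and
predictors — is in this package.  Confidence intervals for fixed
effects are Wald intervals.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

#: Predictors accepted by :func:`univariable_lmm`, matching the
#: columns produced by :func:`assemble_cohort_table`.
COHORT_PREDICTORS = (
    "baseline_area_mm2",
    "baseline_perimeter_mm",
    "baseline_lesion_count",
    "baseline_multifocal",
    "fellow_eye_ga",
    "baseline_circularity",
    "border_fovea_dist_mm",
)

COHORT_OUTCOMES = ("area_growth_rate_mm2_per_yr", "eye_ber_mm_per_yr")


@dataclasses.dataclass(frozen=True)
class MixedModelResult:
    """Fixed effects with Wald 95% CIs, variance components, and fit
    diagnostics from one linear mixed-effects model."""

    fixed_effects: pd.DataFrame  # index: term; columns: estimate, ci_low, ci_high, p
    variance_components: dict[str, float]
    converged: bool
    n_obs: int
    n_patients: int
    formula: str
    simplified: bool = False  # random-effects structure reduced on singular fit

    def term(self, name: str) -> pd.Series:
        return self.fixed_effects.loc[name]


def perimeter_adjusted_growth_rate(
    area0_mm2: float,
    area1_mm2: float,
    perimeter0_mm: float,
    perimeter1_mm: float,
    interval_years: float,
) -> float:
    """Area change divided by the mean perimeter, per year (mm/y).

    An estimator of mean border advance that needs only area and
    perimeter at the two visits.
    """
    if interval_years <= 0:
        raise ValueError("interval must be positive")
    mean_perimeter = (perimeter0_mm + perimeter1_mm) / 2.0
    if mean_perimeter <= 0:
        raise ValueError("mean perimeter is zero: no border to normalize by")
    return (area1_mm2 - area0_mm2) / mean_perimeter / interval_years


def assemble_cohort_table(eye_summaries: list[dict]) -> pd.DataFrame:
    """One row per eye, feeding the univariable mixed models.

    Each summary dict must carry: patient_id, eye_id, baseline
    area/perimeter/lesion_count/circularity, border_fovea_dist_mm,
    area at both visits, eye-specific BER, interval, and (optionally)
    fellow_eye_ga.  Derived columns: ``baseline_multifocal``,
    ``area_growth_rate_mm2_per_yr``, ``perimeter_adjusted_rate_mm_per_yr``.
    """
    table = pd.DataFrame(eye_summaries)
    table["baseline_multifocal"] = (table["baseline_lesion_count"] >= 2).astype(int)
    table["area_growth_rate_mm2_per_yr"] = (
        table["followup_area_mm2"] - table["baseline_area_mm2"]
    ) / table["interval_years"]
    table["perimeter_adjusted_rate_mm_per_yr"] = [
        perimeter_adjusted_growth_rate(a0, a1, p0, p1, dt)
        for a0, a1, p0, p1, dt in zip(
            table["baseline_area_mm2"],
            table["followup_area_mm2"],
            table["baseline_perimeter_mm"],
            table["followup_perimeter_mm"],
            table["interval_years"],
        )
    ]
    if "fellow_eye_ga" not in table:
        table["fellow_eye_ga"] = np.nan
    return table


def _fit_result(fit, formula: str, n_patients: int, simplified: bool) -> MixedModelResult:
    ci = fit.conf_int()
    fe = pd.DataFrame(
        {
            "estimate": fit.fe_params,
            "ci_low": ci.loc[fit.fe_params.index, 0],
            "ci_high": ci.loc[fit.fe_params.index, 1],
            "p": fit.pvalues[fit.fe_params.index],
        }
    )
    vc = {"residual": float(fit.scale)}
    cov_re = pd.DataFrame(fit.cov_re)
    for i, name in enumerate(cov_re.index):
        vc[f"re_{name}"] = float(np.asarray(cov_re)[i, i])
    vc_names = fit.model.exog_vc.names if hasattr(fit.model, "exog_vc") else []
    for name, value in zip(vc_names, np.atleast_1d(fit.vcomp)):
        vc[f"vc_{name}"] = float(value)
    return MixedModelResult(
        fixed_effects=fe,
        variance_components=vc,
        converged=bool(fit.converged),
        n_obs=int(fit.nobs),
        n_patients=n_patients,
        formula=formula,
        simplified=simplified,
    )


def univariable_lmm(
    table: pd.DataFrame, outcome: str, predictor: str
) -> MixedModelResult:
    """Univariable LMM of an eye-level outcome on one baseline factor.

    The eye is the unit of analysis and patients contribute a random
    intercept.  ``outcome`` is one of ``area_growth_rate_mm2_per_yr``
    or ``eye_ber_mm_per_yr``.
    """
    if outcome not in table.columns:
        raise ValueError(f"unknown outcome column: {outcome!r}")
    if predictor not in table.columns:
        raise ValueError(f"unknown predictor column: {predictor!r}")
    data = table[["patient_id", outcome, predictor]].dropna()
    if data["patient_id"].nunique() < 2:
        raise ValueError("need at least 2 patients")
    formula = f"{outcome} ~ {predictor}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["patient_id"])
        fit = model.fit(reml=True)
    if not fit.converged:
        logger.warning("mixed model did not converge: %s", formula)
    return _fit_result(fit, formula, data["patient_id"].nunique(), simplified=False)


def eccentricity_lmm(zone_rows: pd.DataFrame) -> MixedModelResult:
    """Zone-level mixed model of local BER against eccentricity.

    ``zone_rows`` has one row per eye per zone with columns
    ``patient_id``, ``eye_id``, ``eccentricity_mm`` (zone midpoint),
    ``mean_ber_mm_per_yr``, and ``baseline_area_mm2``.  Fixed effects:
    eccentricity and baseline area.  Random effects: intercept and
    eccentricity slope at the patient level (unstructured covariance)
    plus an eye-level random intercept nested within patients.  If the
    full structure fails to converge or is singular, the patient-level
    slope is dropped and the fit repeated, with ``simplified=True``.
    """
    required = {
        "patient_id",
        "eye_id",
        "eccentricity_mm",
        "mean_ber_mm_per_yr",
        "baseline_area_mm2",
    }
    missing = required - set(zone_rows.columns)
    if missing:
        raise ValueError(f"zone_rows is missing columns: {sorted(missing)}")
    data = zone_rows.dropna(subset=["mean_ber_mm_per_yr"]).copy()
    within = data.groupby("eye_id")["eccentricity_mm"].nunique()
    if (within < 2).all():
        raise ValueError(
            "no eye spans more than one eccentricity zone; the "
            "eccentricity effect is not identifiable"
        )
    formula = "mean_ber_mm_per_yr ~ eccentricity_mm + baseline_area_mm2"
    vc = {"eye": "0 + C(eye_id)"}

    def _try(re_formula: str):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(
                formula,
                data,
                groups=data["patient_id"],
                re_formula=re_formula,
                vc_formula=vc,
            )
            return model.fit(reml=True)

    simplified = False
    try:
        fit = _try("1 + eccentricity_mm")
        cov_re = np.asarray(fit.cov_re)
        singular = not fit.converged or np.linalg.cond(cov_re) > 1e8 or np.any(
            np.diag(cov_re) < 1e-12
        )
    except (np.linalg.LinAlgError, ValueError):
        singular = True
        fit = None
    if singular:
        logger.warning(
            "patient-level random slope is singular; refitting with "
            "random intercepts only"
        )
        fit = _try("1")
        simplified = True
    return _fit_result(
        fit, formula, data["patient_id"].nunique(), simplified=simplified
    )


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman rank test across related treatments.

    ``matrix`` is blocks x treatments (e.g. eyes x quadrants) and must
    be complete.  Uses mid-ranks for ties and the chi-square
    approximation.  A matrix whose blocks are all fully tied carries
    no ranking information: statistic 0, p = 1.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need a complete blocks x treatments matrix, >= 2x2")
    if np.isnan(matrix).any():
        raise ValueError("matrix has missing cells; restrict to complete blocks")
    if np.all(matrix == matrix[:, [0]], axis=1).all():
        return 0.0, 1.0
    statistic, p = sps.friedmanchisquare(*matrix.T)
    return float(statistic), float(p)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); 1 when both masks are empty."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(
            f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}"
        )
    total = int(mask_a.sum()) + int(mask_b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / total


def icc_two_way_single(measurements: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC.

    ``measurements`` is subjects x raters, complete.  From the
    standard mean-square decomposition::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater, and MSE the
    residual mean squares.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a complete subjects x raters matrix, >= 2x2")
    if np.isnan(x).any():
        raise ValueError("matrix has missing cells")
    n, k = x.shape
    grand = x.mean()
    if np.allclose(x, grand):
        raise ValueError("zero total variance: ICC undefined")
    subject_means = x.mean(axis=1)
    rater_means = x.mean(axis=0)
    ss_subjects = k * ((subject_means - grand) ** 2).sum()
    ss_raters = n * ((rater_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_error = ss_total - ss_subjects - ss_raters
    msr = ss_subjects / (n - 1)
    msc = ss_raters / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def table_one(table: pd.DataFrame) -> pd.DataFrame:
    """Univariable mixed-model estimates for every baseline factor and
    both growth outcomes, one row per (outcome, predictor)."""
    rows = []
    for outcome in COHORT_OUTCOMES:
        for predictor in COHORT_PREDICTORS:
            if predictor not in table.columns:
                continue
            if table[predictor].nunique(dropna=True) < 2:
                continue  # constant or all-missing factor carries no contrast
            result = univariable_lmm(table, outcome, predictor)
            term = result.term(predictor)
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": predictor,
                    "estimate": term["estimate"],
                    "ci_low": term["ci_low"],
                    "ci_high": term["ci_high"],
                    "p": float(f"{term['p']:.3g}"),
                    "n_eyes": result.n_obs,
                    "n_patients": result.n_patients,
                    "converged": result.converged,
                }
            )
    return pd.DataFrame(rows)
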