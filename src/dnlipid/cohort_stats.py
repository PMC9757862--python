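"""Discovery and regression workflow for the lipid matrix and cohort table.

Two stages mirror the study's statistical analysis:

* **Discovery** — per-species two-group comparison between GDM and euglycemic
  samples (Student's t by default, Welch optional) with the modified
  Bonferroni threshold 0.05/sqrt(n) for n highly interdependent lipid
  variables, combined with a sparse PLS-DA loading ranking: a species is
  "relevant" when it sits in the top 10 loadings and its p-value is below the
  corrected threshold.

* **Regression** — the two report grids. Grid one: each DNL-panel species
  (standardized, as outcome) against maternal characteristics (BMI, OGTT
  glucose at 0/1/2 h, insulin-resistance index), unadjusted. Grid two:
  neonatal outcomes (LGA by logistic regression; birthweight percentile and
  abdominal circumference by linear regression) against each panel species
  (plus a total-triglyceride aggregate) per 1 SD of exposure, under four
  adjustment sets (unadjusted; +BMI; +fasting glucose; fully adjusted for
  age, BMI, parity, ethnicity, fasting glucose, neonatal sex and trial arm,
  plus gestational age at birth for abdominal circumference).

All regressions are complete-case; skewed exposures are log-transformed
before standardization.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .processing import LipidMatrix

logger = logging.getLogger(__name__)

#: Default de-novo-lipogenesis panel: 9 di/triglycerides built from the
#: DNL-related acyls 16:0, 16:1, 18:0 and 18:1.
DEFAULT_DNL_PANEL: tuple[str, ...] = (
    "DG(32:0)",
    "DG(32:1)",
    "DG(34:1)",
    "TG(46:0)",
    "TG(46:1)",
    "TG(48:0)",
    "TG(48:1)",
    "TG(50:1)",
    "TG(50:2)",
)

ADJUSTMENT_SETS = ("unadjusted", "bmi", "fasting_glucose", "full")

SKEWNESS_LOG_CUTOFF = 2.0


@dataclass(frozen=True)
class DnlPanel:
    species: tuple[str, ...] = DEFAULT_DNL_PANEL

    def __iter__(self):
        return iter(self.species)


@dataclass
class RegressionResult:
    outcome_id: str
    exposure_id: str
    model: str  # "linear" | "logistic"
    adjustment_set: str
    estimate: float  # coefficient (linear) or odds ratio (logistic)
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int


class PerfectSeparationError(RuntimeError):
    """Logistic fit diverged: the exposure perfectly separates the outcome."""


# ---------------------------------------------------------------------------
# Multiple-testing threshold
# ---------------------------------------------------------------------------


def modified_bonferroni_threshold(n_vars: int) -> float:
    """Significance limit 0.05 / sqrt(n) for n co-correlated lipid variables.

    The square-root correction allows for the strong interdependence of lipid
    variables; at n = 430 it gives ~0.0024, conventionally applied as 0.002.
    """
    if n_vars < 1:
        raise ValueError(f"n_vars must be >= 1, got {n_vars}")
    return 0.05 / math.sqrt(n_vars)


# ---------------------------------------------------------------------------
# Discovery: t-tests + sparse PLS-DA loading ranks
# ---------------------------------------------------------------------------


def group_t_tests(
    matrix: LipidMatrix | pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-sample t-test per variable between label groups.

    Equal-variance Student form by default; ``equal_var=False`` gives Welch.
    Returns a frame indexed by variable with columns ``mean_case``,
    ``mean_control``, ``t``, ``p``, ``degenerate``. Variables with zero
    variance in both groups are flagged and reported with p = 1.
    """
    values = matrix.values if isinstance(matrix, LipidMatrix) else matrix
    labels = np.asarray(labels, dtype=bool)
    if labels.shape[0] != values.shape[0]:
        raise ValueError("labels length does not match number of samples")
    case, ctrl = values[labels], values[~labels]
    if len(case) < 2 or len(ctrl) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for var in values.columns:
        a, b = case[var].dropna(), ctrl[var].dropna()
        degenerate = a.var(ddof=1) == 0 and b.var(ddof=1) == 0
        if degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        rows.append(
            {
                "variable": var,
                "mean_case": float(a.mean()),
                "mean_control": float(b.mean()),
                "t": float(t),
                "p": float(p),
                "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows).set_index("variable")


def plsda_loadings(
    matrix: LipidMatrix | pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    n_components: int = 2,
    keep_per_component: int | None = None,
) -> pd.DataFrame:
    """Sparse PLS-DA loading magnitudes and ranks per variable.

    NIPALS-style PLS with the centered class indicator as response and
    column-standardized X. Sparsity: each X-weight vector is soft-thresholded
    so only its ``keep_per_component`` largest-|.| entries survive (default
    10 % of variables, minimum 10). Variables are ranked (1 = most important)
    by their maximum absolute weight across components; fully deterministic.
    Constant columns are dropped with a warning and ranked last with zero
    loading.
    """
    values = matrix.values if isinstance(matrix, LipidMatrix) else matrix
    y = np.asarray(labels, dtype=float)
    if y.shape[0] != values.shape[0]:
        raise ValueError("labels length does not match number of samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    sd = values.std(ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant column(s) before PLS-DA",
            stacklevel=2,
        )
    kept_cols = list(values.columns[~constant])
    X = values[kept_cols].to_numpy(float)
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    yc = y - y.mean()
    n, p = X.shape
    if keep_per_component is None:
        keep_per_component = max(10, int(round(0.1 * p)))
    keep_per_component = min(keep_per_component, p)

    max_abs_w = np.zeros(p)
    for _ in range(n_components):
        w = X.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        if keep_per_component < p:
            thresh = np.sort(np.abs(w))[-(keep_per_component + 1)]
            w = np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)
            if not np.any(w):
                break
        w = w / np.linalg.norm(w)
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            break
        p_load = X.T @ t / tt
        c = float(yc @ t) / tt
        X = X - np.outer(t, p_load)  # regression-mode deflation
        yc = yc - c * t
        max_abs_w = np.maximum(max_abs_w, np.abs(w))

    loading = pd.Series(0.0, index=values.columns)
    loading[kept_cols] = max_abs_w
    # rank 1 = largest |loading|; ties broken by column order for determinism
    order = np.lexsort((np.arange(len(loading)), -loading.to_numpy()))
    rank = np.empty(len(loading), dtype=int)
    rank[order] = np.arange(1, len(loading) + 1)
    return pd.DataFrame(
        {"loading": loading, "loading_rank": rank}, index=values.columns
    )


def select_relevant(
    discovery: pd.DataFrame,
    n_vars: int | None = None,
    top_rank: int = 10,
) -> pd.DataFrame:
    """Flag relevant species: loading rank <= 10 AND p below 0.05/sqrt(n)."""
    n_vars = n_vars if n_vars is not None else len(discovery)
    thr = modified_bonferroni_threshold(n_vars)
    out = discovery.copy()
    out["relevant"] = (out["loading_rank"] <= top_rank) & (out["p"] < thr)
    out.attrs["p_threshold"] = thr
    return out


def discover(
    matrix: LipidMatrix | pd.DataFrame,
    labels: Sequence[bool] | pd.Series,
    n_components: int = 2,
    keep_per_component: int | None = None,
    equal_var: bool = True,
) -> pd.DataFrame:
    """t-tests + sPLS-DA ranks + relevance flags in one discovery table."""
    tt = group_t_tests(matrix, labels, equal_var=equal_var)
    ranks = plsda_loadings(matrix, labels, n_components, keep_per_component)
    return select_relevant(tt.join(ranks))


# ---------------------------------------------------------------------------
# Exposure preparation
# ---------------------------------------------------------------------------


def prepare_exposure(
    column: pd.Series, skew_cutoff: float = SKEWNESS_LOG_CUTOFF
) -> pd.Series:
    """Standardize a lipid column to mean 0 / SD 1 on its complete cases.

    Highly skewed columns (|skewness| > 2 by default) are natural-log
    transformed first; zeros are replaced by half the minimum positive value
    so the log is defined.
    """
    x = column.dropna().astype(float)
    if x.var(ddof=1) == 0:
        raise ValueError(f"exposure {column.name!r} has zero variance")
    if abs(scipy.stats.skew(x)) > skew_cutoff:
        pos_min = x[x > 0].min()
        x = np.log(x.where(x > 0, 0.5 * pos_min))
    out = (x - x.mean()) / x.std(ddof=1)
    return out.reindex(column.index)


# ---------------------------------------------------------------------------
# Regression models
# ---------------------------------------------------------------------------


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < X.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        q, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in range(len(diag)) if diag[i] < 1e-10 * diag.max()]
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear columns: {bad}"
        )


def _design(
    exposure: pd.Series,
    covariates: pd.DataFrame | None,
) -> pd.DataFrame:
    X = pd.DataFrame({"exposure": exposure.astype(float)})
    if covariates is not None and covariates.shape[1]:
        X = pd.concat([X, covariates.astype(float)], axis=1)
    X.insert(0, "const", 1.0)
    return X


def linear_regression(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjustment_set: str = "unadjusted",
    outcome_id: str | None = None,
    exposure_id: str | None = None,
) -> RegressionResult:
    """OLS of the outcome on the exposure (+ covariates), complete-case.

    Returns the exposure coefficient with a t-based 95 % CI and p-value.
    Raises on rank-deficient designs, naming the collinear columns.
    """
    X = _design(exposure, covariates)
    data = pd.concat([outcome.rename("__y__"), X], axis=1).dropna()
    n_used = len(data)
    if n_used < X.shape[1] + 2:
        raise ValueError(
            f"too few complete cases ({n_used}) for {X.shape[1]} parameters"
        )
    _check_rank(data[X.columns])
    fit = sm.OLS(data["__y__"], data[X.columns]).fit()
    ci = fit.conf_int().loc["exposure"]
    return RegressionResult(
        outcome_id=outcome_id or str(outcome.name),
        exposure_id=exposure_id or str(exposure.name),
        model="linear",
        adjustment_set=adjustment_set,
        estimate=float(fit.params["exposure"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["exposure"]),
        n_used=n_used,
    )


def logistic_regression(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    adjustment_set: str = "unadjusted",
    outcome_id: str | None = None,
    exposure_id: str | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> RegressionResult:
    """Maximum-likelihood logistic fit (Newton/IRLS), odds-ratio scale.

    The estimate and Wald 95 % CI are exponentiated: odds ratio per unit (for
    a standardized exposure, per 1 SD). Perfect separation is detected and
    raised as :class:`PerfectSeparationError` rather than reported as a
    number.
    """
    X = _design(exposure, covariates)
    data = pd.concat([outcome.rename("__y__"), X], axis=1).dropna()
    n_used = len(data)
    y = data["__y__"].astype(float)
    if y.nunique() < 2:
        raise ValueError("outcome has a single class among complete cases")
    _check_rank(data[X.columns])
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", sm.tools.sm_exceptions.ConvergenceWarning)
        try:
            fit = sm.Logit(y, data[X.columns]).fit(
                disp=False, method="newton", maxiter=max_iter, tol=tol
            )
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
        ) as exc:
            raise PerfectSeparationError(str(exc)) from exc
    coef = float(fit.params["exposure"])
    if (
        abs(coef) > 30
        or not np.isfinite(fit.bse["exposure"])
        or not fit.mle_retvals.get("converged", True)
    ):
        raise PerfectSeparationError(
            "diverging or non-converged fit indicates (quasi-)separation"
        )
    ci = fit.conf_int().loc["exposure"]
    return RegressionResult(
        outcome_id=outcome_id or str(outcome.name),
        exposure_id=exposure_id or str(exposure.name),
        model="logistic",
        adjustment_set=adjustment_set,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(ci[0])),
        ci_high=float(np.exp(ci[1])),
        p_value=float(fit.pvalues["exposure"]),
        n_used=n_used,
    )


# ---------------------------------------------------------------------------
# Adjustment sets and the report grids
# ---------------------------------------------------------------------------


def build_adjustment_covariates(
    cohort: pd.DataFrame,
    adjustment_set: str,
    include_ga_birth: bool = False,
) -> pd.DataFrame | None:
    """Covariate block for one adjustment set.

    Ethnicity enters as indicator contrasts against White (the largest
    group); parity as the nulliparous indicator. The fully adjusted model
    adds gestational age at birth when ``include_ga_birth`` (used for the
    abdominal-circumference outcome).
    """
    if adjustment_set == "unadjusted":
        return None
    if adjustment_set == "bmi":
        return cohort[["bmi"]].astype(float)
    if adjustment_set == "fasting_glucose":
        return cohort[["glucose_0h"]].astype(float)
    if adjustment_set != "full":
        raise ValueError(f"unknown adjustment set {adjustment_set!r}")
    cov = pd.DataFrame(index=cohort.index)
    cov["age"] = cohort["age"].astype(float)
    cov["bmi"] = cohort["bmi"].astype(float)
    cov["nulliparous"] = cohort["nulliparous"].astype(float)
    eth = pd.get_dummies(cohort["ethnicity"], prefix="ethnicity", dtype=float)
    ref = "ethnicity_White"
    cov = pd.concat([cov, eth.drop(columns=[ref], errors="ignore")], axis=1)
    cov["glucose_0h"] = cohort["glucose_0h"].astype(float)
    cov["neonatal_sex_female"] = (cohort["neonatal_sex"] == "female").astype(float)
    cov["trial_arm_intervention"] = (cohort["trial_arm"] == "intervention").astype(
        float
    )
    if include_ga_birth:
        cov["gestational_age_birth"] = cohort["gestational_age_birth"].astype(float)
    return cov


def _matrix_column_for_species(values: pd.DataFrame, species: str) -> str | None:
    if species in values.columns:
        return species
    hits = [c for c in values.columns if c.split("|")[0] == species]
    return hits[0] if hits else None


def total_tg_exposure(values: pd.DataFrame) -> pd.Series:
    """Sum of all TG variables per sample, then standardized (1 SD units)."""
    tg_cols = [c for c in values.columns if c.startswith("TG(")]
    if not tg_cols:
        raise ValueError("no TG variables in matrix")
    total = values[tg_cols].sum(axis=1)
    total.name = "Total triglycerides"
    return prepare_exposure(total)


def run_table_suites(
    matrix: LipidMatrix | pd.DataFrame,
    cohort: pd.DataFrame,
    panel: DnlPanel | Sequence[str] = DnlPanel(),
) -> dict:
    """The two report grids over the DNL panel.

    Grid ``maternal`` (one row per panel species x maternal characteristic):
    linear regression with the standardized species as outcome and the
    characteristic as the single explanatory variable.

    Grid ``neonatal`` (panel species + total-TG aggregate x outcome x
    adjustment set): LGA by logistic regression, birthweight percentile and
    abdominal circumference by linear regression, per 1 SD of exposure.

    Panel species absent from the matrix are reported in ``missing`` rather
    than dropped silently; outcomes with no usable complete cases are emitted
    as all-missing rows with n_used = 0.
    """
    values = matrix.values if isinstance(matrix, LipidMatrix) else matrix
    common = values.index.intersection(cohort.index)
    if len(common) == 0:
        raise ValueError("matrix and cohort share no sample ids")
    values = values.loc[common]
    cohort = cohort.loc[common]

    species_cols: dict[str, str] = {}
    missing: list[str] = []
    for sp in panel:
        col = _matrix_column_for_species(values, sp)
        if col is None:
            missing.append(sp)
        else:
            species_cols[sp] = col

    exposures: dict[str, pd.Series] = {
        sp: prepare_exposure(values[col]).rename(sp)
        for sp, col in species_cols.items()
    }
    try:
        exposures["Total triglycerides"] = total_tg_exposure(values)
    except ValueError:
        missing.append("Total triglycerides")

    maternal_chars = {
        "bmi": "BMI",
        "glucose_0h": "Glucose 0h",
        "glucose_1h": "Glucose 1h",
        "glucose_2h": "Glucose 2h",
        "insulin_resistance_index": "Insulin resistance index",
    }
    maternal_rows = []
    for sp, exposure in exposures.items():
        if sp == "Total triglycerides" and sp in missing:
            continue
        for col, label in maternal_chars.items():
            res = linear_regression(
                exposure, cohort[col].astype(float),
                outcome_id=sp, exposure_id=label,
            )
            maternal_rows.append(vars(res))
    maternal = pd.DataFrame(maternal_rows)

    outcome_specs = [
        ("lga", "logistic", False),
        ("birthweight_percentile", "linear", False),
        ("abdominal_circumference", "linear", True),
    ]
    neonatal_rows = []
    for out_col, model, ga_adj in outcome_specs:
        y = cohort[out_col]
        y = y.astype(float) if model == "linear" else y.astype("boolean").astype("Int64")
        for sp, exposure in exposures.items():
            for adj in ADJUSTMENT_SETS:
                cov = build_adjustment_covariates(cohort, adj, include_ga_birth=ga_adj)
                try:
                    if model == "logistic":
                        res = logistic_regression(
                            y.astype(float), exposure, cov, adj,
                            outcome_id=out_col, exposure_id=sp,
                        )
                    else:
                        res = linear_regression(
                            y, exposure, cov, adj,
                            outcome_id=out_col, exposure_id=sp,
                        )
                    neonatal_rows.append(vars(res))
                except (ValueError, PerfectSeparationError, np.linalg.LinAlgError):
                    neonatal_rows.append(
                        {
                            "outcome_id": out_col,
                            "exposure_id": sp,
                            "model": model,
                            "adjustment_set": adj,
                            "estimate": float("nan"),
                            "ci_low": float("nan"),
                            "ci_high": float("nan"),
                            "p_value": float("nan"),
                            "n_used": 0,
                        }
                    )
    neonatal = pd.DataFrame(neonatal_rows)
    if missing:
        logger.warning("panel species missing from matrix: %s", missing)
    return {"maternal": maternal, "neonatal": neonatal, "missing": missing}
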