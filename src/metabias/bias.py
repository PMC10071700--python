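"""Per-meta-analysis publication-bias detection and correction.

For each meta-analysis this module fits:

* the intercept-only multilevel model (overall, uncorrected mean);
* an extended Egger-type multilevel meta-regression of effect size on its
  uncertainty (standard error or the effective-sample predictor) and on
  centred publication year — the linear *detection* model, whose slopes
  flag small-study effects (uncertainty slope) and decline effects (year
  slope);
* the quadratic *correction* model, which replaces the uncertainty term by
  its square (sampling variance / inverse effective sample) so that the
  intercept, conditional on zero sampling error and the latest publication
  year, is a PET/PEESE-style bias-corrected overall effect.

Because heterogeneity can flip the slope signs away from what selective
publication predicts, a decision tree chooses among the full quadratic
model, two reduced models, and the plain intercept-only model before the
corrected intercept is read off (the "type 2" estimate); the full-model
intercept is always kept as the "type 1" estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .effect_sizes import effective_sample_predictor
from .multilevel import MultilevelMetaRegression

__all__ = [
    "BiasCaseResult",
    "expected_signs",
    "fit_bias_models",
    "apply_decision_tree",
    "analyze_meta",
]


def expected_signs(beta0_overall_sign: float) -> tuple[int, int]:
    """Slope signs implied by publication bias, given the overall-effect sign.

    A positive overall effect under selective publication implies a positive
    uncertainty slope (small studies overshoot upward) and a negative year
    slope (published effects decline); a negative overall effect mirrors
    both.  A zero overall effect leaves both indeterminate, encoded as 0.
    """
    s = np.sign(beta0_overall_sign)
    if s > 0:
        return (1, -1)
    if s < 0:
        return (-1, 1)
    return (0, 0)


def _error_predictors(df: pd.DataFrame, predictor_mode: str) -> tuple[np.ndarray, np.ndarray, str]:
    """Linear and quadratic uncertainty predictors for the bias models.

    Modes: "auto" uses the effective-sample predictor for SMD / lnRR when
    every record carries both group sizes, otherwise the standard error;
    "effective_n" forces the former (erroring if sizes are missing);
    "se" forces the standard error / sampling variance.
    """
    metric = df["metric"].iloc[0]
    se = np.sqrt(df["var"].to_numpy(dtype=float))
    have_n = (
        {"n_e", "n_c"}.issubset(df.columns)
        and df["n_e"].notna().all()
        and df["n_c"].notna().all()
    )
    use_n = False
    if predictor_mode == "effective_n":
        if not have_n:
            raise ValueError("effective_n predictor requested but group sizes missing")
        use_n = True
    elif predictor_mode == "auto":
        use_n = have_n and metric in ("SMD", "lnRR")
    elif predictor_mode != "se":
        raise ValueError(f"unknown predictor_mode {predictor_mode!r}")
    if use_n:
        lin = effective_sample_predictor(df["n_e"], df["n_c"], "linear")
        quad = effective_sample_predictor(df["n_e"], df["n_c"], "quadratic")
        mode = "effective_n"
    else:
        lin, quad, mode = se, se**2, "se"
    return np.asarray(lin, float), np.asarray(quad, float), mode


def _fit_case_models(
    y, v, groups, err_lin, err_quad, year_c, inference="z"
) -> dict:
    """Fit the null, linear-detection and quadratic-correction models.

    `year_c` must already be centred on the latest year (or its
    standardized analogue).  Constant predictor columns are dropped with a
    record of what was dropped.  Returns a dict of fitted estimators plus
    bookkeeping.
    """
    dropped = []
    null = MultilevelMetaRegression(inference=inference).fit(None, y, v=v, groups=groups)

    def _moderators(err_col):
        cols, names = [], []
        if np.ptp(err_col) > 0:
            cols.append(err_col)
            names.append("error")
        else:
            dropped.append("error")
        if np.ptp(year_c) > 0:
            cols.append(year_c)
            names.append("year")
        elif "year" not in dropped:
            dropped.append("year")
        return (np.column_stack(cols) if cols else None), names

    X_lin, names_lin = _moderators(err_lin)
    X_quad, names_quad = _moderators(err_quad)
    linear = MultilevelMetaRegression(inference=inference).fit(
        X_lin, y, v=v, groups=groups, names=names_lin
    )
    quadratic = MultilevelMetaRegression(inference=inference).fit(
        X_quad, y, v=v, groups=groups, names=names_quad
    )
    return {
        "null": null,
        "linear": linear,
        "quadratic": quadratic,
        "names_linear": names_lin,
        "names_quadratic": names_quad,
        "dropped": sorted(set(dropped)),
        "_refit": lambda X, names: MultilevelMetaRegression(inference=inference).fit(
            X, y, v=v, groups=groups, names=names
        ),
        "_cols": {"err_quad": err_quad, "year_c": year_c},
    }


def fit_bias_models(df: pd.DataFrame, predictor_mode: str = "auto", inference: str = "z") -> dict:
    """Fit the detection (linear) and correction (quadratic) models for one
    meta-analysis given as a validated record table."""
    if len(df) < 4:
        raise ValueError(f"bias models need k >= 4 effect sizes, got {len(df)}")
    y = df["es"].to_numpy(dtype=float)
    v = df["var"].to_numpy(dtype=float)
    groups = df["study_id"].to_numpy()
    err_lin, err_quad, mode = _error_predictors(df, predictor_mode)
    if "year" in df.columns and df["year"].notna().all():
        year = df["year"].to_numpy(dtype=float)
        year_c = year - year.max()
    else:
        year_c = np.zeros(len(df))
    fits = _fit_case_models(y, v, groups, err_lin, err_quad, year_c, inference)
    fits["predictor_mode"] = mode
    return fits


def apply_decision_tree(
    fits: dict, expected: tuple[int, int], variant: str = "main_text"
) -> tuple[str, MultilevelMetaRegression]:
    """Select the corrected-intercept model from the slope sign pattern.

    Detection uses the *linear* model's slopes.  Scenarios:

    1. both slopes in the expected direction -> full quadratic model;
    2. uncertainty slope expected, year slope not -> reduced model with the
       quadratic uncertainty term only;
    3. uncertainty slope unexpected, year slope expected -> reduced model
       with the year term only;
    4. both unexpected -> the intercept-only (uncorrected) model.

    ``variant="figure_caption"`` swaps which sign pattern is sent to which
    reduced model (scenarios 2 and 3 exchange their refits).
    If the year (or uncertainty) term was dropped as constant, the decision
    collapses to the remaining slope.  Indeterminate expectations (overall
    effect exactly zero) keep the full model and warn.
    """
    linear = fits["linear"]
    names = fits["names_linear"]
    exp_err, exp_year = expected
    if exp_err == 0 and exp_year == 0:
        warnings.warn(
            "overall effect is exactly zero: expected slope signs are "
            "indeterminate; keeping the full-model corrected intercept",
            stacklevel=2,
        )
        return "full", fits["quadratic"]

    tab = linear.coef_table()
    err_ok = year_ok = None
    if "error" in names:
        err_ok = np.sign(tab.loc["error", "estimate"]) == exp_err
    if "year" in names:
        year_ok = np.sign(tab.loc["year", "estimate"]) == exp_year

    cols = fits["_cols"]

    def reduced_error():
        return fits["_refit"](cols["err_quad"][:, None], ["error"])

    def reduced_year():
        return fits["_refit"](cols["year_c"][:, None], ["year"])

    if err_ok is None and year_ok is None:
        return "4", fits["null"]
    if err_ok is None:
        return ("3", reduced_year()) if year_ok else ("4", fits["null"])
    if year_ok is None:
        return ("2", reduced_error()) if err_ok else ("4", fits["null"])

    if err_ok and year_ok:
        return "1", fits["quadratic"]
    if not err_ok and not year_ok:
        return "4", fits["null"]
    if variant == "figure_caption":
        # caption mapping: unexpected uncertainty slope -> drop *year* term
        return ("2", reduced_error()) if not err_ok else ("3", reduced_year())
    return ("2", reduced_error()) if err_ok else ("3", reduced_year())


@dataclass
class BiasCaseResult:
    """One meta-analysis' bias-detection and correction summary."""

    meta_id: str
    metric: str
    k: int
    n_studies: int
    predictor_mode: str
    beta0_overall: float
    se_overall: float
    p_overall: float
    beta1_small_study: float | None
    se_beta1: float | None
    p_beta1: float | None
    beta2_time_lag: float | None
    se_beta2: float | None
    p_beta2: float | None
    beta0_corrected_type1: float
    se_corrected_type1: float
    p_corrected_type1: float
    beta0_corrected_type2: float
    se_corrected_type2: float
    p_corrected_type2: float
    scenario: str
    expected_sign_beta1: int
    expected_sign_beta2: int
    sigma2_study: float
    sigma2_obs: float
    dropped_terms: str

    def to_dict(self) -> dict:
        return asdict(self)


def _slope(tab: pd.DataFrame, name: str):
    if name in tab.index:
        row = tab.loc[name]
        return float(row["estimate"]), float(row["se"]), float(row["pval"])
    return None, None, None


def analyze_meta(
    df: pd.DataFrame,
    predictor_mode: str = "auto",
    variant: str = "main_text",
    inference: str = "z",
) -> BiasCaseResult:
    """Run the full per-meta-analysis bias workflow on one record table."""
    meta_id = str(df["meta_id"].iloc[0])
    fits = fit_bias_models(df, predictor_mode=predictor_mode, inference=inference)
    null_tab = fits["null"].coef_table()
    b0 = float(null_tab.loc["intercept", "estimate"])
    expected = expected_signs(b0)
    lin_tab = fits["linear"].coef_table()
    quad_tab = fits["quadratic"].coef_table()
    scenario, corrected = apply_decision_tree(fits, expected, variant=variant)
    corr_tab = corrected.coef_table()

    b1, se1, p1 = _slope(lin_tab, "error")
    b2, se2, p2 = _slope(lin_tab, "year")
    return BiasCaseResult(
        meta_id=meta_id,
        metric=str(df["metric"].iloc[0]),
        k=len(df),
        n_studies=df["study_id"].nunique(),
        predictor_mode=fits["predictor_mode"],
        beta0_overall=b0,
        se_overall=float(null_tab.loc["intercept", "se"]),
        p_overall=float(null_tab.loc["intercept", "pval"]),
        beta1_small_study=b1,
        se_beta1=se1,
        p_beta1=p1,
        beta2_time_lag=b2,
        se_beta2=se2,
        p_beta2=p2,
        beta0_corrected_type1=float(quad_tab.loc["intercept", "estimate"]),
        se_corrected_type1=float(quad_tab.loc["intercept", "se"]),
        p_corrected_type1=float(quad_tab.loc["intercept", "pval"]),
        beta0_corrected_type2=float(corr_tab.loc["intercept", "estimate"]),
        se_corrected_type2=float(corr_tab.loc["intercept", "se"]),
        p_corrected_type2=float(corr_tab.loc["intercept", "pval"]),
        scenario=scenario,
        expected_sign_beta1=expected[0],
        expected_sign_beta2=expected[1],
        sigma2_study=fits["null"].sigma2_study_,
        sigma2_obs=fits["null"].sigma2_obs_,
        dropped_terms=",".join(fits["dropped"]),
    )
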