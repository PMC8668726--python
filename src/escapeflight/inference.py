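"""Mixed-effects inference on the per-flight analysis table.

Repeated escape flights of the same bird are not independent, so every model
carries a bird-level random intercept and is fitted by REML (statsmodels
MixedLM).  Three model families mirror the study design:

* M1: fictive disk loading ~ treatment * sex * day
* M2: escape speed ~ disk loading * treatment * day (fitted twice, with the
  fictive and with the real loading)
* M3: wingbeat frequency ~ disk loading * treatment * day

plus three post-hoc analyses: (a) fictive loading vs. a tagged/untagged
factor and its day interaction, (b) pairwise treatment differences in speed
with no covariates, and (c) tagged-vs-untagged speed, with and without day
and real-loading covariates.

Because the factorial models contain interactions with an uncentered
covariate, raw main-effect coefficients are evaluated at loading = 0 — far
outside the data.  Slopes are therefore reported as *average partial
effects*: the mean of the model derivative over the observed design (what
``emmeans::emtrends`` reports), which for an interaction-free truth equals
the generating slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices

TREATMENT_LEVELS = ("control", "lighter_tag", "heavier_tag")


class InferenceError(ValueError):
    """The analysis table or a requested contrast is invalid."""


@dataclass
class FitResult:
    """A fitted mixed (or plain OLS) model in portable form."""

    name: str
    formula: str
    fe_params: pd.Series
    fe_se: pd.Series
    random_intercept_var: float
    residual_var: float
    converged: bool
    singular: bool = False
    n_obs: int = 0
    n_groups: int = 0
    design_info: object = None   # patsy design info for the fixed effects

    def coef_table(self) -> pd.DataFrame:
        z = self.fe_params / self.fe_se
        # large-sample normal (Wald); exact small-sample denominator dfs are
        # implementation-specific and deliberately not reproduced
        from scipy.stats import norm
        return pd.DataFrame({
            "estimate": self.fe_params, "se": self.fe_se, "z": z,
            "p": 2 * norm.sf(np.abs(z)),
        })

    def to_jsonable(self) -> dict:
        return {
            "name": self.name, "formula": self.formula,
            "fixed_effects": self.fe_params.to_dict(),
            "fixed_effects_se": self.fe_se.to_dict(),
            "random_intercept_var": self.random_intercept_var,
            "residual_var": self.residual_var,
            "converged": self.converged, "singular": self.singular,
            "n_obs": self.n_obs, "n_groups": self.n_groups,
        }


REQUIRED_COLUMNS = ("bird_id", "sex", "treatment", "tagged", "test_day",
                    "loading_fictive", "loading_real", "U", "f")


def build_analysis_table(cohort: pd.DataFrame,
                         loading_records: pd.DataFrame) -> pd.DataFrame:
    """One row per flight with every modelled column, types normalised."""
    tab = loading_records.merge(
        cohort[["bird_id", "sex", "treatment"]], on="bird_id", how="left",
        validate="many_to_one", suffixes=("", "_cohort"))
    tab = tab.rename(columns={"mean_speed": "U", "wingbeat_freq": "f",
                              "test_day": "test_day"})
    tab["tagged"] = (tab["treatment"] != "control")
    return _validate_table(tab)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InferenceError(f"analysis table missing columns: {missing}")
    tab = table.copy()
    tab["treatment"] = pd.Categorical(tab["treatment"],
                                      categories=TREATMENT_LEVELS)
    if tab["treatment"].isna().any():
        raise InferenceError(f"unknown treatment levels; expected {TREATMENT_LEVELS}")
    tab["day"] = tab["test_day"].astype(float)
    tab["tagged"] = tab["tagged"].astype(int)
    modeled = ["loading_fictive", "loading_real", "U", "f", "day"]
    if tab[modeled].isna().any().any():
        raise InferenceError("missing values in modelled columns")
    return tab


def _fit_mixedlm(formula: str, table: pd.DataFrame, name: str) -> FitResult:
    """REML fit with a bird random intercept; falls back to OLS (variance
    structure collapsed) if the optimiser fails outright."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, table, groups=table["bird_id"])
        res = None
        for method in ("bfgs", "powell", "nm"):
            try:
                candidate = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if candidate.converged:
                res = candidate
                break
    if res is not None and res.converged:
        re_var = float(np.asarray(res.cov_re).ravel()[0])
        singular = re_var < 1e-10
        return FitResult(
            name=name, formula=formula,
            fe_params=res.fe_params.copy(),
            fe_se=res.bse_fe.copy(),
            random_intercept_var=max(re_var, 0.0),
            residual_var=float(res.scale),
            converged=True, singular=singular,
            n_obs=int(res.nobs), n_groups=len(model.group_labels),
            design_info=model.data.design_info)
    # fall back to a simplified (independence) variance structure
    warnings.warn(f"mixed model {name!r} did not converge; "
                  "falling back to OLS variance structure")
    ols = smf.ols(formula, table).fit()
    return FitResult(
        name=name, formula=formula, fe_params=ols.params.copy(),
        fe_se=ols.bse.copy(), random_intercept_var=0.0,
        residual_var=float(ols.mse_resid), converged=False, singular=True,
        n_obs=int(ols.nobs), n_groups=table["bird_id"].nunique(),
        design_info=ols.model.data.design_info)


def fit_main_models(table: pd.DataFrame) -> dict[str, FitResult]:
    """Fit the three model families (M2 in both loading variants).

    Day enters as a numeric covariate; sex is excluded from the speed and
    frequency models because it is collinear with disk loading.
    """
    tab = _validate_table(table)
    fits = {
        "loading": _fit_mixedlm(
            "loading_fictive ~ treatment * sex * day", tab, "loading"),
        "speed_fictive": _fit_mixedlm(
            "U ~ loading_fictive * treatment * day", tab, "speed_fictive"),
        "speed_real": _fit_mixedlm(
            "U ~ loading_real * treatment * day", tab, "speed_real"),
        "freq": _fit_mixedlm(
            "f ~ loading_real * treatment * day", tab, "freq"),
    }
    return fits


def posthoc_contrasts(table: pd.DataFrame) -> dict[str, FitResult]:
    """The three post-hoc analyses.

    (a) does fictive loading drift over time differently for tagged birds;
    (b) pairwise treatment differences in speed, no covariates;
    (c) tagged-vs-untagged speed, alone and with day + real loading.
    """
    tab = _validate_table(table)
    fits = {
        "a_loading_tagged_day": _fit_mixedlm(
            "loading_fictive ~ sex + tagged + day + tagged:day", tab,
            "a_loading_tagged_day"),
        "c_speed_tagged": _fit_mixedlm("U ~ tagged", tab, "c_speed_tagged"),
        "c_speed_tagged_day": _fit_mixedlm(
            "U ~ tagged + day + loading_real + tagged:day", tab,
            "c_speed_tagged_day"),
    }
    pairs = [("control", "lighter_tag"), ("control", "heavier_tag"),
             ("lighter_tag", "heavier_tag")]
    for t1, t2 in pairs:
        sub = tab[tab["treatment"].isin([t1, t2])].copy()
        sub["treatment"] = pd.Categorical(sub["treatment"], categories=[t1, t2])
        fits[f"b_speed_{t1}_vs_{t2}"] = _fit_mixedlm(
            "U ~ treatment", sub, f"b_speed_{t1}_vs_{t2}")
    return fits


# ---------------------------------------------------------------------------
# slope extraction and summaries


def average_partial_effect(fit: FitResult, table: pd.DataFrame, var: str,
                           subset=None, delta: float = 1.0) -> float:
    """Average partial effect of a numeric covariate: mean of d(fit)/d(var)
    over the observed rows (optionally a boolean subset).

    The model is linear, so the derivative is computed exactly from the
    design-matrix difference at ``var`` and ``var + delta``.
    """
    if fit.design_info is None:
        raise InferenceError("fit carries no design information")
    tab = _validate_table(table)
    if subset is not None:
        tab = tab.loc[np.asarray(subset)]
        if len(tab) == 0:
            raise InferenceError("empty subset for partial effect")
    X0 = np.asarray(build_design_matrices([fit.design_info], tab)[0])
    tab2 = tab.copy()
    tab2[var] = tab2[var] + delta
    X1 = np.asarray(build_design_matrices([fit.design_info], tab2)[0])
    beta = fit.fe_params.to_numpy()
    return float(np.mean((X1 - X0) @ beta) / delta)


def day_slope_by_treatment(fit: FitResult, table: pd.DataFrame) -> dict[str, float]:
    """Marginal per-day slope within each treatment group."""
    tab = _validate_table(table)
    return {tr: average_partial_effect(fit, tab, "day",
                                       subset=(tab["treatment"] == tr).to_numpy())
            for tr in TREATMENT_LEVELS}


def summarize_group_effects(table: pd.DataFrame,
                            fits: dict[str, FitResult] | None = None) -> dict:
    """Bird-level group summaries and the headline percentages.

    Means are taken per bird first, then across birds (SE over birds, not
    flights).  The tagged-vs-untagged percent reduction and the percent
    change over the study (day 1 -> day 28, a 27-day span) are reported
    rounded to the precision the field uses.
    """
    tab = _validate_table(table)
    bird_means = tab.groupby("bird_id", observed=True).agg(
        U=("U", "mean"), f=("f", "mean"), tagged=("tagged", "first"),
        treatment=("treatment", "first"), sex=("sex", "first"))
    out = {"groups": {}}
    for label, sub in (("untagged", bird_means[bird_means.tagged == 0]),
                       ("tagged", bird_means[bird_means.tagged == 1])):
        if len(sub) == 0:
            raise InferenceError(f"no birds in group {label!r}")
        out["groups"][label] = {
            "U_mean": float(sub.U.mean()),
            "U_se": float(sub.U.std(ddof=1) / np.sqrt(len(sub))),
            "f_mean": float(sub.f.mean()),
            "n_birds": int(len(sub)),
        }
    out["percent_speed_reduction_tagged"] = percent_group_reduction(
        out["groups"]["untagged"]["U_mean"], out["groups"]["tagged"]["U_mean"])
    if fits is not None and "freq" in fits:
        slope = average_partial_effect(fits["freq"], tab, "day")
        baseline = float(bird_means.f.mean())
        out["freq_day_slope"] = slope
        out["percent_freq_change_over_study"] = percent_change_over_study(
            slope, baseline, n_days=int(tab["day"].max() - tab["day"].min()))
    return out


def percent_group_reduction(u_untagged: float, u_tagged: float) -> int:
    """Tagged-vs-untagged percent speed reduction, rounded to integer
    (half away from zero)."""
    if u_untagged <= 0:
        raise InferenceError("reference group mean must be positive")
    pct = 100.0 * (u_untagged - u_tagged) / u_untagged
    import math
    return int(math.floor(abs(pct) + 0.5)) * (1 if pct >= 0 else -1)


def percent_change_over_study(slope_per_day: float, baseline: float,
                              n_days: int = 27) -> float:
    """Percent change implied by a daily slope over the study span, as a
    fraction of the baseline value, rounded to 1 decimal.

    The default span is 27 days (day 1 to day 28); the result is reported at
    a precision robust to the 27-vs-28-day ambiguity in how such spans are
    quoted.
    """
    if baseline <= 0:
        raise InferenceError("baseline must be positive")
    return round(100.0 * slope_per_day * n_days / baseline, 1)
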