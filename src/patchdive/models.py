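"""The mixed-model hypothesis battery.

Eight linear mixed models (random intercept per bird, colony as a fixed
effect, maximum-likelihood fits) test, in order:

1. dive IPQ ~ bottom vertical distance            (IPQ validation)
2. bout IPQ ~ number of dives in the bout         (IPQ validation)
3. dive IPQ ~ in-bout flag                        (IPQ validation)
4. bout IPQ ~ distance to colony                  (depletion halo)
5. near-colony bout IPQ ~ date                    (seasonal change)
6. forage dive depth ~ breeding stage
7. max trip distance ~ breeding stage
8. max trip distance ~ start date, per stage

IPQ responses are square-root transformed (once) before fitting.
Significance comes from likelihood-ratio tests against the same model
without the predictor; models 4-8 additionally test the colony effect and
are refitted per colony when it is significant.  Transition-stage birds
(stage changed between deployment and retrieval) are excluded from models
6-8.  When every bird contributes at most one observation the random
effect is unidentifiable and a plain linear model is used instead
(flagged in the result).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .tracks import julian_day

logger = logging.getLogger(__name__)

__all__ = ["ModelResult", "near_colony_radius", "fit_lmm", "run_battery"]

ALPHA = 0.05


@dataclass
class ModelResult:
    model_id: str
    scope: str  # "all" or a colony name
    response: str
    predictor: str
    slope: float
    slope_se: float
    lrt_chi2: float
    lrt_df: int
    p_value: float
    colony_lrt_chi2: float | None
    colony_lrt_df: int | None
    colony_p: float | None
    n_obs: int
    n_birds: int
    used_lm_fallback: bool

    def to_dict(self):
        return asdict(self)


def near_colony_radius(trips: pd.DataFrame, max_duration_h: float = 24.0) -> float:
    """Median maximum distance (km) of sub-day trips: the 'near colony' radius."""
    sub = trips[trips["duration_h"] < max_duration_h]
    if len(sub) == 0:
        raise ValueError("no sub-day trips; near-colony radius undefined")
    return float(sub["max_distance"].median())


def _loglik(result) -> float:
    return float(result.llf)


def _fit_ml(formula: str, data: pd.DataFrame, group_col: str | None):
    """ML fit: MixedLM with random intercept, or OLS when group_col is None."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if group_col is None:
            return smf.ols(formula, data=data).fit()
        model = smf.mixedlm(formula, data=data, groups=data[group_col])
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=200)
            if not np.isfinite(res.llf):
                raise ValueError("non-finite log-likelihood")
            return res
        except Exception:
            return model.fit(reml=False, method="powell", maxiter=500)


def fit_lmm(
    data: pd.DataFrame,
    response: str,
    predictor: str,
    group_col: str = "bird_id",
    colony_col: str = "colony",
    sqrt_response: bool = False,
    model_id: str = "",
    scope: str = "all",
    categorical_predictor: bool = False,
) -> ModelResult:
    """One battery entry: ML fit, predictor LRT, colony LRT.

    ``sqrt_response`` applies the square-root transform here (exactly once;
    callers pass raw IPQ).  Falls back to a linear model, flagged in the
    result, when every bird contributes at most one observation or the
    mixed fit is singular.
    """
    df = data[[c for c in {response, predictor, group_col, colony_col} if c in data.columns]].dropna().copy()
    if len(df) < 8:
        raise ValueError(f"model {model_id}: too few observations ({len(df)})")
    if not np.isfinite(df[response].to_numpy(dtype=float)).all():
        bad = df.index[~np.isfinite(df[response].astype(float))].tolist()
        raise ValueError(f"non-finite response at rows {bad[:10]}")
    yname = response
    if sqrt_response:
        if (df[response] < 0).any():
            raise ValueError("negative response; cannot sqrt-transform")
        yname = f"sqrt_{response}"
        df[yname] = np.sqrt(df[response].astype(float))

    pred_term = f"C({predictor})" if categorical_predictor else predictor
    n_colonies = df[colony_col].nunique() if colony_col in df.columns else 1
    colony_term = f" + C({colony_col})" if n_colonies > 1 else ""

    per_bird = df.groupby(group_col).size()
    use_lm = bool((per_bird <= 1).all())
    grp = None if use_lm else group_col

    full = _fit_ml(f"{yname} ~ {pred_term}{colony_term}", df, grp)
    if grp is not None and not _converged(full):
        logger.warning("model %s: singular mixed fit; refitting without random effect", model_id)
        use_lm, grp = True, None
        full = _fit_ml(f"{yname} ~ {pred_term}{colony_term}", df, grp)
    null = _fit_ml(f"{yname} ~ 1{colony_term}", df, grp)

    if categorical_predictor:
        levels = sorted(df[predictor].unique())
        pred_df = len(levels) - 1
        # contrast of the last level vs the reference (e.g. incubation - brood)
        name = f"C({predictor})[T.{levels[-1]}]"
    else:
        pred_df = 1
        name = predictor
    slope = float(full.params[name])
    slope_se = float(full.bse[name])
    chi2 = max(2.0 * (_loglik(full) - _loglik(null)), 0.0)
    p = float(stats.chi2.sf(chi2, pred_df))

    colony_chi2 = colony_df = colony_p = None
    if n_colonies > 1:
        no_col = _fit_ml(f"{yname} ~ {pred_term}", df, grp)
        colony_df = n_colonies - 1
        colony_chi2 = max(2.0 * (_loglik(full) - _loglik(no_col)), 0.0)
        colony_p = float(stats.chi2.sf(colony_chi2, colony_df))

    return ModelResult(
        model_id=model_id,
        scope=scope,
        response=yname,
        predictor=predictor,
        slope=slope,
        slope_se=slope_se,
        lrt_chi2=float(chi2),
        lrt_df=pred_df,
        p_value=p,
        colony_lrt_chi2=colony_chi2,
        colony_lrt_df=colony_df,
        colony_p=colony_p,
        n_obs=int(len(df)),
        n_birds=int(df[group_col].nunique()),
        used_lm_fallback=use_lm,
    )


def _converged(res) -> bool:
    try:
        if not np.isfinite(res.llf):
            return False
        if hasattr(res, "cov_re"):
            return bool(np.all(np.isfinite(np.asarray(res.bse_fe))))
        return True
    except Exception:
        return False


def _with_per_colony(results, df, alpha, **kwargs):
    """Append per-colony refits when the colony effect is significant."""
    head = results[-1]
    if head.colony_p is not None and head.colony_p < alpha:
        for colony, sub in df.groupby("colony"):
            try:
                results.append(fit_lmm(sub, scope=str(colony), **kwargs))
            except ValueError as err:
                logger.info("per-colony refit skipped: %s", err)
    return results


def run_battery(
    dives: pd.DataFrame,
    bouts: pd.DataFrame,
    trips: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Execute models 1-8 with their subset rules; one row per model x scope.

    Expects the pipeline's dive table (forage dives carry ipq, in_bout,
    bottom_vertical_distance, stage, colony), bout table (n_dives,
    mean_dist, mean_ipq, t_start) and trip table (max_distance, duration_h,
    stage, start date).  Models that lack their subset are skipped with a
    logged reason.
    """
    results: list[ModelResult] = []
    forage = dives[(dives["dive_type"] == "forage") & dives["ipq"].notna()].copy()
    bouts = bouts.copy()
    bouts["start_julian"] = bouts["t_start"].map(julian_day).astype(float)
    trips = trips.copy()
    if "start_julian" not in trips.columns:
        trips["start_julian"] = trips["t_start"].map(julian_day).astype(float)

    def attempt(fn, model_id):
        try:
            fn()
        except ValueError as err:
            logger.warning("model %s skipped: %s", model_id, err)

    attempt(lambda: results.append(fit_lmm(
        forage, "ipq", "bottom_vertical_distance", sqrt_response=True, model_id="1")), "1")
    attempt(lambda: results.append(fit_lmm(
        bouts, "mean_ipq", "n_dives", sqrt_response=True, model_id="2")), "2")

    d3 = dives[(dives["dive_type"] == "forage") & dives["ipq"].notna()].copy()
    d3["in_bout_int"] = d3["in_bout"].astype(int)
    attempt(lambda: results.append(fit_lmm(
        d3, "ipq", "in_bout_int", sqrt_response=True, model_id="3")), "3")

    def model4(tag, sub):
        kw = dict(response="mean_ipq", predictor="mean_dist", sqrt_response=True, model_id=tag)
        results.append(fit_lmm(sub, **kw))
        _with_per_colony(results, sub, alpha, **kw)

    attempt(lambda: model4("4", bouts), "4")
    if "stage" in bouts.columns:
        for st in ("brood", "incubation"):
            sub = bouts[bouts["stage"] == st]
            if len(sub) >= 8:
                attempt(lambda s=sub, t=st: model4(f"4_{t}", s), f"4_{st}")

    def model5():
        parts = []
        for colony, sub in bouts.groupby("colony"):
            radius = near_colony_radius(trips[trips["colony"] == colony])
            parts.append(sub[sub["mean_dist"] <= radius])
        near = pd.concat(parts, ignore_index=True)
        kw = dict(response="mean_ipq", predictor="start_julian", sqrt_response=True, model_id="5")
        results.append(fit_lmm(near, **kw))
        _with_per_colony(results, near, alpha, **kw)

    attempt(model5, "5")

    staged_dives = forage[forage["stage"].isin(["incubation", "brood"])]
    staged_trips = trips[trips["stage"].isin(["incubation", "brood"])]

    def model6():
        kw = dict(response="max_depth", predictor="stage", categorical_predictor=True, model_id="6")
        results.append(fit_lmm(staged_dives, **kw))
        _with_per_colony(results, staged_dives, alpha, **kw)

    attempt(model6, "6")

    def model7():
        kw = dict(response="max_distance", predictor="stage", categorical_predictor=True, model_id="7")
        results.append(fit_lmm(staged_trips, **kw))
        _with_per_colony(results, staged_trips, alpha, **kw)

    attempt(model7, "7")

    for st in ("incubation", "brood"):
        sub = staged_trips[staged_trips["stage"] == st]

        def model8(sub=sub, st=st):
            kw = dict(response="max_distance", predictor="start_julian", model_id=f"8_{st}")
            results.append(fit_lmm(sub, **kw))
            _with_per_colony(results, sub, alpha, **kw)

        attempt(model8, f"8_{st}")

    return pd.DataFrame([r.to_dict() for r in results])
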