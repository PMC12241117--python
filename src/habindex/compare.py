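"""Statistical comparison of the weighting schemes.

Two analyses mirror the two data situations:

* **Annual indices** — the Distribution Index series are compared
  across weighting methods with a linear mixed model,
  ``di ~ method`` with random intercepts for habitat and for year
  nested within habitat (``compare_di``).  The reference level is the
  unweighted scheme, so each fixed-effect coefficient is that method's
  estimated shift of the index relative to Unw.  Per-habitat models
  (year as the random intercept) give the habitat-resolved contrasts.

* **Overall trends** — species trends are stacked into
  (species, habitat, method, trend, weight) rows and fitted by weighted
  least squares, ``trend ~ habitat * method`` with the scheme's own
  weights (``compare_trends``).  The ANOVA table tests habitat, method
  and their interaction; estimated marginal means per habitat x method
  cell with 95% CIs correspond, for this saturated design, to the
  weighted cell means.

Mixed models are fitted by REML via statsmodels; t-test degrees of
freedom use the residual approximation (noted in the result metadata —
no Satterthwaite correction is applied).  p-values are reported raw,
with no multiple-testing correction.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .weighting import METHODS

__all__ = [
    "compare_di",
    "compare_trends",
    "significance_summary",
]

logger = logging.getLogger(__name__)

EMMEANS_COLUMNS = ["habitat", "method", "mean", "se", "ci_low", "ci_high"]


def _method_categorical(s: pd.Series) -> pd.Series:
    present = [m for m in METHODS if m in set(s)] + sorted(set(s) - set(METHODS))
    return pd.Categorical(s, categories=present, ordered=True)


def _mixedlm_fixed_table(result, model_name: str) -> pd.DataFrame:
    k_fe = result.k_fe
    params = result.fe_params
    se = result.bse.iloc[:k_fe]
    df_resid = result.nobs - k_fe
    tvals = params / se
    from scipy import stats

    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    terms = [t.replace("C(method)[T.", "").replace("]", "") for t in params.index]
    terms = ["Intercept (Unw)" if t == "Intercept" else t for t in terms]
    return pd.DataFrame(
        {
            "model": model_name,
            "term": terms,
            "estimate": params.to_numpy(),
            "se": se.to_numpy(),
            "df": df_resid,
            "stat": tvals.to_numpy(),
            "p": pvals,
        }
    )


def compare_di(index: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Mixed-model comparison of Distribution Index across methods.

    Parameters
    ----------
    index
        Distribution Index table (habitat, method, year, di, ...), at
        least 2 methods, habitats and years.

    Returns
    -------
    dict with:

    ``overall``
        fixed-effect table (model, term, estimate, se, df, stat, p) of
        ``di ~ method`` with habitat and year-within-habitat random
        intercepts; reference level Unw.
    ``per_habitat``
        the same contrast table per habitat (year random intercept),
        with an extra ``habitat`` column.
    ``meta``
        single-row table: convergence/singularity flags and the df
        approximation used.
    """
    data = index.copy()
    data["method"] = _method_categorical(data["method"])
    data["year_f"] = data["year"].astype(str)
    if data["method"].nunique() < 2:
        raise ValueError("need at least two methods to compare")

    singular = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "di ~ C(method)",
            data,
            groups="habitat",
            re_formula="1",
            vc_formula={"year_f": "0 + C(year_f)"},
        )
        result = model.fit(reml=True)
        if getattr(result, "converged", True) is False:
            singular.append("overall")
    overall = _mixedlm_fixed_table(result, "di_mixed")

    per_rows = []
    for habitat, grp in data.groupby("habitat", sort=True):
        if grp["year"].nunique() < 2 or grp["method"].nunique() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = smf.mixedlm("di ~ C(method)", grp, groups="year_f", re_formula="1")
            r = m.fit(reml=True)
            if getattr(r, "converged", True) is False:
                singular.append(habitat)
        tab = _mixedlm_fixed_table(r, "di_mixed_per_habitat")
        tab.insert(0, "habitat", habitat)
        per_rows.append(tab)
    per_habitat = (
        pd.concat(per_rows, ignore_index=True) if per_rows else pd.DataFrame()
    )
    meta = pd.DataFrame(
        {
            "df_method": ["residual"],
            "reml": [True],
            "non_converged": [";".join(map(str, singular))],
        }
    )
    return {"overall": overall, "per_habitat": per_habitat, "meta": meta}


def stack_trend_design(
    trends: pd.DataFrame, weights: pd.DataFrame, period: str
) -> pd.DataFrame:
    """Join one trend period with the weight table into the WLS design.

    One row per (species, habitat, method) with positive weight; raises
    if a weighted species lacks a trend for the period, and warns when a
    habitat is populated under one method but empty under another.
    """
    tr = trends.loc[trends["period"] == period, ["species", "trend"]]
    w = weights.loc[weights["weight"] > 0]
    design = w.merge(tr, on="species", how="inner")
    cells = design.groupby(["habitat", "method"], sort=False).size().unstack()
    if cells.isna().any().any():
        logger.warning(
            "unbalanced design: some habitat x method cells are empty:\n%s",
            cells[cells.isna().any(axis=1)],
        )
    return design.reset_index(drop=True)


def compare_trends(
    trends: pd.DataFrame,
    weights: pd.DataFrame,
    period: str = "long",
) -> dict[str, pd.DataFrame]:
    """Weighted least-squares comparison of habitat trends across methods.

    Fits ``trend ~ habitat * method`` with each scheme's own weights.
    Returns a dict with ``anova`` (terms habitat, method, interaction
    with F statistics and p-values), ``emmeans`` (estimated marginal
    mean, SE and 95% CI per habitat x method cell) and ``design`` (the
    stacked rows actually fitted).
    """
    design = stack_trend_design(trends, weights, period)
    design = design.copy()
    design["method"] = _method_categorical(design["method"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.wls(
            "trend ~ C(habitat) * C(method)",
            data=design,
            weights=design["weight"].to_numpy(),
        ).fit()
        anova = anova_lm(fit, typ=2)
    anova_tab = pd.DataFrame(
        {
            "model": "trend_linear",
            "term": ["habitat", "method", "interaction", "residual"],
            "df": anova["df"].to_numpy(),
            "stat": anova["F"].to_numpy(),
            "p": anova["PR(>F)"].to_numpy(),
        }
    )

    grid = (
        design.groupby(["habitat", "method"], sort=True, observed=True)
        .size()
        .reset_index()[["habitat", "method"]]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pred = fit.get_prediction(grid).summary_frame(alpha=0.05)
    emmeans = pd.DataFrame(
        {
            "habitat": grid["habitat"].to_numpy(),
            "method": grid["method"].astype(str).to_numpy(),
            "mean": pred["mean"].to_numpy(),
            "se": pred["mean_se"].to_numpy(),
            "ci_low": pred["mean_ci_lower"].to_numpy(),
            "ci_high": pred["mean_ci_upper"].to_numpy(),
        }
    )[EMMEANS_COLUMNS]
    return {"anova": anova_tab, "emmeans": emmeans, "design": design}


def significance_summary(emmeans: pd.DataFrame) -> pd.DataFrame:
    """Classify each habitat x method trend by its 95% CI against zero.

    Adds a ``direction`` column: ``positive`` (CI above 0), ``negative``
    (CI below 0) or ``indistinguishable`` (CI straddles 0).
    """
    out = emmeans.copy()
    out["direction"] = np.where(
        out["ci_low"] > 0,
        "positive",
        np.where(out["ci_high"] < 0, "negative", "indistinguishable"),
    )
    return out
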