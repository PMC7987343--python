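"""Diversity-stability and asynchrony-stability regressions.

`fit_assoc` regresses a per-mesocosm stability response on a per-mesocosm
predictor (richness, diversity index, species stability or synchrony) with
soil-inoculum origin nested within experimental blocks as random terms.
`sterile_contrast` asks whether a relationship is driven solely by the
sterile (0 um) treatment: an indicator for the sterile level is entered
*before* the continuous predictor and the residual predictor effect is
tested sequentially.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["AssocFit", "fit_assoc", "sterile_contrast"]


@dataclass
class AssocFit:
    response: str
    predictor: str
    slope: float
    se: float
    p: float
    n: int
    method: str  # 'mixed', 'ols', or 'ols+blocks'
    grouping: str
    # sterile-contrast fields (populated by sterile_contrast)
    contrast_estimate: float = float("nan")
    contrast_p: float = float("nan")
    residual_slope: float = float("nan")
    residual_p: float = float("nan")
    contrast_skipped: bool = False
    notes: list = field(default_factory=list)


def _frame(response, predictor, design, response_name, predictor_name):
    df = design.copy()
    df["y"] = df["mesocosm"].map(pd.Series(response)).astype(float)
    df["x"] = df["mesocosm"].map(pd.Series(predictor)).astype(float)
    n_before = len(df)
    df = df.dropna(subset=["y", "x"])
    if n_before - len(df):
        log.info(
            "%s ~ %s: dropped %d incomplete mesocosms",
            response_name, predictor_name, n_before - len(df),
        )
    return df


def fit_assoc(
    response: pd.Series,
    predictor: pd.Series,
    design: pd.DataFrame,
    response_name: str = "response",
    predictor_name: str = "predictor",
) -> AssocFit:
    """Slope, SE and Wald p for predictor -> response.

    With >1 origin or block a linear mixed model is fitted (random intercepts
    for block and origin-within-block); with a single level of both it
    reduces to ordinary least squares.  A mixed fit that fails or is singular
    falls back to OLS with origin/block as fixed covariates (logged).
    """
    import statsmodels.formula.api as smf

    df = _frame(response, predictor, design, response_name, predictor_name)
    if len(df) < 3:
        raise ValueError("too few complete mesocosms to fit")
    simple = df["origin"].nunique() == 1 and df["block"].nunique() == 1
    notes = []
    if simple:
        res = smf.ols("y ~ x", data=df).fit()
        method, grouping = "ols", "none"
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = smf.mixedlm(
                    "y ~ x", data=df, groups=df["block"],
                    re_formula="1", vc_formula={"origin": "0 + C(origin)"},
                )
                res = model.fit(reml=True)
            if not np.isfinite(res.bse["x"]):
                raise RuntimeError("singular mixed fit")
            method, grouping = "mixed", "origin within block (random)"
        except Exception as err:
            log.info("mixed model failed (%s); falling back to fixed blocks", err)
            notes.append(f"mixed-model fallback: {err}")
            res = smf.ols("y ~ x + C(origin) + C(block)", data=df).fit()
            method, grouping = "ols+blocks", "origin, block (fixed)"
    return AssocFit(
        response=response_name,
        predictor=predictor_name,
        slope=float(res.params["x"]),
        se=float(res.bse["x"]),
        p=float(res.pvalues["x"]),
        n=len(df),
        method=method,
        grouping=grouping,
        notes=notes,
    )


def sterile_contrast(
    response: pd.Series,
    predictor: pd.Series,
    design: pd.DataFrame,
    response_name: str = "response",
    predictor_name: str = "predictor",
) -> AssocFit:
    """Test the predictor effect after first accounting for the sterile level.

    Sequential (type-I) ANOVA on an OLS model with blocking covariates:
    terms enter as origin + block + sterile-indicator + predictor, so the
    reported residual predictor effect is conditional on the sterile
    contrast.  Skipped (flagged) when the design has no sterile mesocosms.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    fit = fit_assoc(response, predictor, design, response_name, predictor_name)
    df = _frame(response, predictor, design, response_name, predictor_name)
    if "sieve_um" in df.columns:
        df["sterile"] = (df["sieve_um"] == 0).astype(float)
    else:
        df["sterile"] = (df["treatment_score"] == 0).astype(float)
    if df["sterile"].sum() == 0:
        fit.contrast_skipped = True
        fit.notes.append("no sterile mesocosms in design; contrast skipped")
        return fit

    blocking = ""
    if df["origin"].nunique() > 1:
        blocking += "C(origin) + "
    if df["block"].nunique() > 1:
        blocking += "C(block) + "
    res = smf.ols(f"y ~ {blocking}sterile + x", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        anova = sm.stats.anova_lm(res, typ=1)
    fit.contrast_estimate = float(res.params["sterile"])
    fit.contrast_p = float(anova.loc["sterile", "PR(>F)"])
    fit.residual_slope = float(res.params["x"])
    fit.residual_p = float(anova.loc["x", "PR(>F)"])
    fit.notes.append("sequential ANOVA: blocking terms, sterile, then predictor")
    return fit
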