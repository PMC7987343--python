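"""Multiple-threshold multifunctionality analysis on temporal stabilities.

For each threshold fraction t of a function's maximum observed stability,
count per mesocosm how many functions reach t x max, regress that count on
the diversity predictor, and trace the slope (with 95% CI) across a grid of
thresholds (default 5%..95% in 1% steps, 91 points).  The summary reports
T_min / T_max — the smallest / largest thresholds with a significantly
positive slope — and R_mde, the threshold where the slope is steepest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "default_grid",
    "functions_above",
    "scan",
    "summarize",
    "ThresholdSummary",
]


def default_grid() -> np.ndarray:
    """Threshold fractions 0.05..0.95 at 0.01 intervals (91 values)."""
    return np.arange(5, 96) / 100.0


def functions_above(stab: pd.DataFrame, t: float) -> pd.Series:
    """Count per mesocosm of functions whose stability reaches t x its maximum.

    ``stab`` is the tidy stability table; degenerate (zero-variance) records
    are excluded both from the per-function maxima and from the counts.
    """
    if not 0 < t <= 1:
        raise ValueError("threshold fraction must be in (0, 1]")
    ok = stab.loc[~stab["degenerate"]]
    maxima = ok.groupby("function", observed=True)["stability"].max()
    cutoff = ok["function"].map(maxima) * t
    hits = ok.loc[ok["stability"] >= cutoff]
    counts = hits.groupby("mesocosm", observed=True).size()
    return counts.reindex(stab["mesocosm"].unique(), fill_value=0).astype(int)


def _fit_count_model(counts, diversity, design, family, n_functions):
    """One per-threshold regression; origin/block enter as fixed blocking
    covariates (no NB mixed-model tooling; downgrade logged once by scan)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = design[["mesocosm", "origin", "block"]].merge(
        pd.DataFrame({"mesocosm": counts.index, "count": counts.to_numpy()}),
        on="mesocosm",
    )
    df["diversity"] = df["mesocosm"].map(
        pd.Series(np.asarray(diversity, dtype=float), index=counts.index)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "nb":
            model_used = "nb"
            try:
                model = smf.negativebinomial(
                    "count ~ diversity + C(origin) + C(block)", data=df
                )
                res = model.fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", False))
                se_probe = float(res.bse["diversity"])
                if not (converged and np.isfinite(se_probe) and se_probe > 0):
                    raise RuntimeError("NB fit did not converge")
            except Exception:
                # dispersion at the Poisson boundary breaks the NB optimizer;
                # NB with alpha -> 0 is exactly Poisson, so refit there
                model_used = "poisson"
                res = smf.glm(
                    "count ~ diversity + C(origin) + C(block)", data=df,
                    family=sm.families.Poisson(),
                ).fit()
                converged = bool(res.converged)
        elif family == "binomial":
            X = sm.add_constant(
                pd.get_dummies(
                    df[["diversity", "origin", "block"]], drop_first=True, dtype=float
                )
            )
            endog = np.column_stack([df["count"], n_functions - df["count"]])
            res = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
            converged = bool(res.converged)
            model_used = "binomial"
        else:
            raise ValueError(f"unknown family {family!r}")
    slope = float(res.params["diversity"])
    se = float(res.bse["diversity"])
    if not np.isfinite(se) or se == 0:
        converged = False
    return slope, se, converged, model_used


def scan(
    diversity: pd.Series,
    stab: pd.DataFrame,
    design: pd.DataFrame,
    grid: np.ndarray | None = None,
    family: str = "nb",
) -> pd.DataFrame:
    """Slope of diversity -> (count of functions above threshold) across a grid.

    Returns one row per threshold: slope, Wald 95% CI, significance (CI
    excluding zero) and a convergence flag; non-converging thresholds are
    recorded and skipped, never fatal.
    """
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if not ((grid > 0) & (grid < 1)).all() or (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly increasing within (0, 1)")
    n_functions = stab["function"].nunique()
    log.info(
        "threshold scan: %d thresholds, family=%s, origin/block as fixed "
        "blocking covariates", len(grid), family,
    )
    div = diversity.reindex(stab["mesocosm"].unique())
    rows = []
    for t in grid:
        counts = functions_above(stab, t)
        row = {
            "threshold": float(t), "slope": np.nan, "se": np.nan,
            "ci_low": np.nan, "ci_high": np.nan,
            "significant": False, "converged": False, "model": None,
        }
        if counts.nunique() > 1:  # constant counts carry no signal
            try:
                slope, se, converged, model_used = _fit_count_model(
                    counts, div.to_numpy(), design, family, n_functions
                )
            except Exception as err:
                log.info("threshold %.2f: fit failed (%s)", t, err)
            else:
                row["model"] = model_used
                if converged:
                    lo, hi = slope - 1.96 * se, slope + 1.96 * se
                    row.update(
                        slope=slope, se=se, ci_low=lo, ci_high=hi,
                        significant=bool(lo > 0 or hi < 0), converged=True,
                    )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdSummary:
    t_min: float  # smallest threshold with significant positive slope (NaN if none)
    t_max: float  # largest such threshold
    r_mde: float  # threshold of steepest slope among significant ones
    any_significant: bool


def summarize(scan_df: pd.DataFrame) -> ThresholdSummary:
    """T_min / T_max / R_mde from a threshold scan (positive slopes only)."""
    ok = scan_df.loc[
        scan_df["converged"] & scan_df["significant"] & (scan_df["slope"] > 0)
    ]
    if ok.empty:
        return ThresholdSummary(float("nan"), float("nan"), float("nan"), False)
    t_min = float(ok["threshold"].min())
    t_max = float(ok["threshold"].max())
    r_mde = float(ok.loc[ok["slope"].idxmax(), "threshold"])
    return ThresholdSummary(t_min, t_max, r_mde, True)
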