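"""Permutation-null standardized effect sizes of taxa on ecosystem functions,
and the accumulation of function-affecting taxa across functions and times.

For one taxon at one harvest, the observed effect on a function is the
difference in mean function value between mesocosms where the taxon is
present and where it is absent.  A null distribution is built by randomly
reassigning the function values across mesocosms (presence fixed) and
recomputing the difference; SES = (observed - null mean) / null SD, and a
taxon is called significant when |SES| > 1.96 (5% two-sided error).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Dataset, split_sample_key

log = logging.getLogger(__name__)

__all__ = [
    "SESResult",
    "AffectingSets",
    "observed_effect",
    "taxon_ses",
    "ses_matrix",
    "accumulation_curve",
    "fit_accumulation",
    "ols_slope",
]

Z_STAR_DEFAULT = 1.96
N_ITER_DEFAULT = 999
MIN_GROUP_DEFAULT = 3


@dataclass(frozen=True)
class SESResult:
    taxon: str
    function: str
    time: int
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when degenerate
    significant: bool
    sign: int  # sign of SES; 0 when not significant or degenerate
    degenerate: bool  # null SD == 0


@dataclass
class AffectingSets:
    """(function, time) -> sets of significantly positive / negative taxa."""

    positive: dict[tuple[str, int], set[str]]
    negative: dict[tuple[str, int], set[str]]

    def by_function(self, function: str, sign: str = "positive") -> dict[int, set[str]]:
        src = self.positive if sign == "positive" else self.negative
        return {t: s for (f, t), s in src.items() if f == function}

    def by_time(self, time: int, sign: str = "positive") -> dict[str, set[str]]:
        src = self.positive if sign == "positive" else self.negative
        return {f: s for (f, t), s in src.items() if t == time}

    def union_positive(self, function: str) -> set[str]:
        """Taxa positively associated with ``function`` at any time."""
        return set().union(*self.by_function(function).values() or [set()])


def eligible(presence, min_group: int = MIN_GROUP_DEFAULT) -> bool:
    """A taxon is testable when both groups hold at least ``min_group`` mesocosms."""
    p = np.asarray(presence, dtype=bool)
    return bool(p.sum() >= min_group and (~p).sum() >= min_group)


def observed_effect(presence, f) -> float:
    """mean(f | taxon present) - mean(f | taxon absent)."""
    p = np.asarray(presence, dtype=bool)
    f = np.asarray(f, dtype=float)
    if not p.any() or p.all():
        raise ValueError("taxon is ubiquitous or absent everywhere")
    return float(f[p].mean() - f[~p].mean())


def taxon_ses(
    presence,
    f,
    n_iter: int = N_ITER_DEFAULT,
    rng: np.random.Generator | None = None,
    zstar: float = Z_STAR_DEFAULT,
    taxon: str = "",
    function: str = "",
    time: int = 0,
) -> SESResult:
    """Permutation SES for one taxon at one (function, time).

    The function values are permuted across mesocosms ``n_iter`` times with
    the presence pattern fixed; the SES standardizes the observed mean
    difference against that null.
    """
    if n_iter < 99:
        raise ValueError("n_iter must be >= 99")
    if rng is None:
        rng = np.random.default_rng()
    p = np.asarray(presence, dtype=bool)
    f = np.asarray(f, dtype=float)
    obs = observed_effect(p, f)
    perms = rng.permuted(np.broadcast_to(f, (n_iter, f.size)), axis=1)
    null = perms[:, p].mean(axis=1) - perms[:, ~p].mean(axis=1)
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        return SESResult(
            taxon, function, time, obs, null_mean, 0.0,
            float("nan"), False, 0, True,
        )
    ses = (obs - null_mean) / null_sd
    significant = abs(ses) > zstar
    return SESResult(
        taxon, function, time, obs, null_mean, null_sd,
        float(ses), bool(significant), int(np.sign(ses)) if significant else 0,
        False,
    )


def _presence_matrix(ds: Dataset, time: int) -> pd.DataFrame:
    """Taxa x mesocosm boolean presence at one harvest (all groups combined)."""
    combined = pd.concat(ds.abundance.values(), axis=0)
    cols = [c for c in combined.columns if split_sample_key(c)[1] == time]
    sub = combined[cols] > 0
    sub.columns = [split_sample_key(c)[0] for c in cols]
    return sub


def ses_matrix(
    ds: Dataset,
    n_iter: int = N_ITER_DEFAULT,
    zstar: float = Z_STAR_DEFAULT,
    min_group: int = MIN_GROUP_DEFAULT,
    seed: int = 0,
    functions: list[str] | None = None,
    times: list[int] | None = None,
) -> tuple[pd.DataFrame, AffectingSets]:
    """SES for every eligible (taxon, function, time) in a dataset.

    Each (function, time, taxon) triple gets its own deterministic RNG
    substream derived from ``seed``, so results are reproducible regardless
    of evaluation order.  Ineligible taxa (fewer than ``min_group``
    mesocosms in either group) are recorded with ``eligible=False``.
    """
    functions = functions or ds.function_names
    times = times or ds.times
    func_wide = ds.functions.pivot_table(
        index="mesocosm", columns=["function", "time"], values="value"
    )
    rows = []
    pos: dict[tuple[str, int], set[str]] = {}
    neg: dict[tuple[str, int], set[str]] = {}
    for ti, t in enumerate(times):
        presence = _presence_matrix(ds, t)
        for fi, fname in enumerate(functions):
            fvals = func_wide[(fname, t)].loc[presence.columns].to_numpy()
            pos[(fname, t)] = set()
            neg[(fname, t)] = set()
            for xi, taxon in enumerate(presence.index):
                p = presence.loc[taxon].to_numpy()
                if not eligible(p, min_group):
                    rows.append(
                        {
                            "taxon": taxon, "function": fname, "time": t,
                            "eligible": False, "degenerate": False,
                            "observed": np.nan, "null_mean": np.nan,
                            "null_sd": np.nan, "ses": np.nan,
                            "significant": False, "sign": 0,
                        }
                    )
                    continue
                rng = np.random.default_rng(
                    np.random.SeedSequence([seed, ti, fi, xi])
                )
                res = taxon_ses(
                    p, fvals, n_iter=n_iter, rng=rng, zstar=zstar,
                    taxon=taxon, function=fname, time=t,
                )
                rows.append(
                    {
                        "taxon": taxon, "function": fname, "time": t,
                        "eligible": True, "degenerate": res.degenerate,
                        "observed": res.observed, "null_mean": res.null_mean,
                        "null_sd": res.null_sd, "ses": res.ses,
                        "significant": res.significant, "sign": res.sign,
                    }
                )
                if res.significant:
                    (pos if res.sign > 0 else neg)[(fname, t)].add(taxon)
    return pd.DataFrame(rows), AffectingSets(pos, neg)


def accumulation_curve(
    sets: dict, denominator: int, max_k: int | None = None
) -> pd.DataFrame:
    """Mean proportion of taxa affecting at least one of k items.

    ``sets`` maps items (functions, or time points) to affecting-taxon sets.
    For each k the mean over all C(K, k) combinations of |union| /
    ``denominator`` is returned; the curve is monotone nondecreasing in k.
    """
    if not sets:
        raise ValueError("accumulation_curve: empty set collection")
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    items = list(sets)
    K = len(items)
    max_k = max_k or K
    rows = []
    for k in range(1, max_k + 1):
        combos = list(itertools.combinations(items, k))
        props = [
            len(set().union(*(sets[i] for i in combo))) / denominator
            for combo in combos
        ]
        rows.append(
            {
                "k": k,
                "proportion": float(np.mean(props)),
                "n_combinations": len(combos),
            }
        )
    return pd.DataFrame(rows)


def ols_slope(y, x) -> float:
    """Least-squares slope of y on x (used for the slope-0 / slope-1 analytics)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.polyfit(x, y, 1)[0])


@dataclass(frozen=True)
class BetaBinFit:
    slope: float  # on the linear predictor (logit) scale
    slope_se: float
    ci_low: float
    ci_high: float
    intercept: float
    rho: float  # beta-binomial overdispersion (0 = binomial)
    method: str  # 'beta-binomial' or 'binomial'
    converged: bool
    loglik: float


def fit_accumulation(successes, trials, k) -> BetaBinFit:
    """Beta-binomial regression of affected-taxon counts on k (logit link).

    Maximizes the beta-binomial likelihood with mean logit-linear in k and a
    common intraclass overdispersion rho; when rho collapses to the binomial
    boundary the fit falls back to a plain binomial GLM.  Non-convergence is
    reported through ``converged``, never silently.
    """
    from scipy import optimize, special, stats
    from statsmodels.tools.numdiff import approx_hess1

    y = np.asarray(successes, dtype=float)
    n = np.asarray(trials, dtype=float)
    x = np.asarray(k, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("fit_accumulation needs >= 2 distinct k values")

    def negll(params):
        b0, b1, logit_rho = params
        mu = special.expit(b0 + b1 * x)
        rho = special.expit(logit_rho)
        a = mu * (1.0 - rho) / rho
        b = (1.0 - mu) * (1.0 - rho) / rho
        with np.errstate(invalid="ignore"):
            ll = stats.betabinom.logpmf(y, n, a, b)
        if not np.isfinite(ll).all():
            return 1e10
        return -float(ll.sum())

    # start from the empirical logit slope
    emp = special.logit(np.clip((y + 0.5) / (n + 1.0), 1e-6, 1 - 1e-6))
    b1_0, b0_0 = np.polyfit(x, emp, 1)
    best = None
    for rho0 in (-4.0, -2.0, -6.0):
        res = optimize.minimize(
            negll, [b0_0, b1_0, rho0], method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    b0, b1, logit_rho = best.x
    rho = float(special.expit(logit_rho))

    if rho < 1e-4:
        return _binomial_fallback(y, n, x, best)

    hess = approx_hess1(best.x, negll)
    try:
        cov = np.linalg.inv(hess)
        se = float(np.sqrt(cov[1, 1])) if cov[1, 1] > 0 else np.nan
    except np.linalg.LinAlgError:
        se = np.nan
    if not np.isfinite(se):
        # overdispersion parameter diverged or Hessian singular
        return _binomial_fallback(y, n, x, best)
    return BetaBinFit(
        slope=float(b1), slope_se=se,
        ci_low=float(b1 - 1.96 * se), ci_high=float(b1 + 1.96 * se),
        intercept=float(b0), rho=rho, method="beta-binomial",
        converged=bool(best.success), loglik=-float(best.fun),
    )


def _binomial_fallback(y, n, x, opt_result) -> BetaBinFit:
    import warnings

    import statsmodels.api as sm

    X = sm.add_constant(x)
    fam = sm.families.Binomial()
    model = sm.GLM(np.column_stack([y, n - y]), X, family=fam)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit()
        ci = res.conf_int()
        return BetaBinFit(
            slope=float(res.params[1]), slope_se=float(res.bse[1]),
            ci_low=float(ci[1][0]), ci_high=float(ci[1][1]),
            intercept=float(res.params[0]), rho=0.0, method="binomial",
            converged=True, loglik=float(res.llf),
        )
    except Exception as err:  # pragma: no cover - surfaced, not swallowed
        log.warning("binomial fallback failed: %s", err)
        return BetaBinFit(
            slope=np.nan, slope_se=np.nan, ci_low=np.nan, ci_high=np.nan,
            intercept=np.nan, rho=np.nan, method="binomial",
            converged=False, loglik=np.nan,
        )
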