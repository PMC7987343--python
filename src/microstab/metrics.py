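"""Stability, diversity, multifunctionality, species-stability and synchrony.

Temporal stability is the inverse coefficient of variation CV^-1 = mu/sigma
of a quantity over the harvests of one mesocosm (sample SD, T-1 divisor).
Synchrony is the mean pairwise covariance of taxon abundance series after
standardizing each to mean 0 and SD 1 — equivalently the mean pairwise
Pearson correlation, bounded in [-1, 1]: values near 1 mean taxa rise and
fall together; negative values mean compensatory (asynchronous) dynamics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "StabilityRecord",
    "temporal_stability",
    "stability_table",
    "richness",
    "richness_table",
    "mean_richness",
    "scale_unit",
    "multifunctional_stability",
    "diversity_index",
    "species_stability",
    "synchrony",
]


@dataclass(frozen=True)
class StabilityRecord:
    mean: float
    sd: float
    stability: float  # mu / sigma; NaN when degenerate
    degenerate: bool  # sigma == 0 (constant series)


def temporal_stability(series) -> StabilityRecord:
    """CV^-1 of one time series: temporal mean over temporal sample SD."""
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("temporal_stability needs at least 2 time points")
    if not np.isfinite(x).all():
        raise ValueError("temporal_stability: non-finite values in series")
    mu = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        return StabilityRecord(mu, 0.0, float("nan"), True)
    return StabilityRecord(mu, sd, mu / sd, False)


def stability_table(functions: pd.DataFrame) -> pd.DataFrame:
    """Per (mesocosm, function): temporal mean, SD, stability, degenerate flag."""
    rows = []
    for (meso, f), grp in functions.groupby(["mesocosm", "function"], observed=True):
        rec = temporal_stability(grp.sort_values("time")["value"].to_numpy())
        rows.append(
            {
                "mesocosm": meso,
                "function": f,
                "mean": rec.mean,
                "sd": rec.sd,
                "stability": rec.stability,
                "degenerate": rec.degenerate,
            }
        )
    return pd.DataFrame(rows)


def richness(abundance_column) -> int:
    """Number of taxa with abundance > 0."""
    a = np.asarray(abundance_column, dtype=float)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative")
    return int((a > 0).sum())


def richness_table(abundance: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Tidy per (group, mesocosm, time) richness from the abundance tables."""
    from .datatypes import split_sample_key

    rows = []
    for group, tab in abundance.items():
        for col in tab.columns:
            meso, t = split_sample_key(col)
            rows.append(
                {
                    "group": group,
                    "mesocosm": meso,
                    "time": t,
                    "richness": richness(tab[col]),
                }
            )
    return pd.DataFrame(rows)


def mean_richness(rich: pd.DataFrame) -> pd.DataFrame:
    """Average richness per mesocosm over all time points, one column per group."""
    wide = rich.pivot_table(
        index="mesocosm", columns="group", values="richness", aggfunc="mean"
    )
    wide.columns.name = None
    return wide.reset_index()


def scale_unit(values) -> np.ndarray:
    """Rescale to [0, 1] via (v - min) / (max - min); constant input -> all 0.5."""
    v = np.asarray(values, dtype=float)
    vmin, vmax = np.nanmin(v), np.nanmax(v)
    if vmax == vmin:
        warnings.warn(
            "scale_unit: constant vector, returning 0.5 for all entries",
            stacklevel=2,
        )
        return np.full_like(v, 0.5)
    return (v - vmin) / (vmax - vmin)


def multifunctional_stability(stab: pd.DataFrame) -> pd.Series:
    """Averaging multifunctionality on stabilities: per-mesocosm mean of
    unit-scaled (across mesocosms) per-function stabilities.

    ``stab`` is the tidy output of :func:`stability_table`.  Mesocosms
    missing (or degenerate in) any function are excluded, with a log entry.
    """
    wide = stab.pivot(index="mesocosm", columns="function", values="stability")
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        log.info(
            "multifunctional_stability: excluding %d mesocosms with missing or "
            "degenerate stabilities", n_dropped,
        )
    scaled = complete.apply(lambda col: scale_unit(col.to_numpy()), axis=0)
    out = scaled.mean(axis=1)
    out.name = "multifunctional_stability"
    return out


def diversity_index(rich: pd.DataFrame) -> pd.Series:
    """Scaled microbial diversity index in [0, 1] per mesocosm.

    Each group's richness is rescaled to [0, 1] *within each time point*,
    then averaged over groups and time points.  A time point where a group's
    richness is constant contributes 0.5 for that group (warned).
    """
    parts = []
    for (group, t), grp in rich.groupby(["group", "time"]):
        scaled = pd.Series(
            scale_unit(grp["richness"].to_numpy()),
            index=grp["mesocosm"].to_numpy(),
        )
        parts.append(scaled)
    index = pd.concat(parts, axis=1).mean(axis=1)
    index.name = "diversity_index"
    index.index.name = "mesocosm"
    return index


def _eligible_series(abund: pd.DataFrame) -> pd.DataFrame:
    """Taxa x times sub-table with nonconstant, somewhere-present series."""
    vals = abund.to_numpy(dtype=float)
    present = vals.sum(axis=1) > 0
    varying = vals.std(axis=1, ddof=1) > 0
    keep = present & varying
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info(
            "excluding %d taxa absent throughout or with zero temporal variance",
            n_dropped,
        )
    return abund.loc[keep]


def species_stability(abund: pd.DataFrame, use_cv: bool = False) -> float:
    """Mean per-taxon temporal stability CV^-1 over a taxa x times table.

    ``use_cv=True`` averages the CV (sigma/mu) instead — the two readings of
    "average coefficient of variation" differ and the inverse is the default
    reported here.  Taxa absent throughout or with zero variance are excluded.
    """
    sub = _eligible_series(abund)
    if sub.empty:
        raise ValueError("species_stability: no eligible taxa")
    vals = sub.to_numpy(dtype=float)
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    ratios = sd / mu if use_cv else mu / sd
    return float(ratios.mean())


def synchrony(abund: pd.DataFrame) -> float:
    """Mean pairwise covariance of standardized taxon series (= mean pairwise
    Pearson correlation) over a taxa x times table."""
    sub = _eligible_series(abund)
    if len(sub) < 2:
        raise ValueError("synchrony needs >= 2 taxa with temporal variance")
    corr = np.corrcoef(sub.to_numpy(dtype=float))
    iu = np.triu_indices_from(corr, k=1)
    return float(corr[iu].mean())


def taxa_series_for(
    abundance: dict[str, pd.DataFrame], mesocosm: str, taxa: set[str]
) -> pd.DataFrame:
    """Time series (taxa x times) of the given taxa within one mesocosm."""
    from .datatypes import split_sample_key

    combined = pd.concat(abundance.values(), axis=0)
    cols = {
        split_sample_key(c)[1]: c
        for c in combined.columns
        if split_sample_key(c)[0] == mesocosm
    }
    ordered = [cols[t] for t in sorted(cols)]
    sub = combined.loc[combined.index.isin(taxa), ordered]
    sub.columns = sorted(cols)
    return sub
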