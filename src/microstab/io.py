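"""Readers, validation and function preprocessing for the experiment tables.

Input layout: a design table (one row per mesocosm), a tidy functions table
(mesocosm, time, function, value) and one taxa x samples abundance table per
organism group, with sample columns keyed ``<mesocosm>_T<time>``.
CSV/TSV dialects are auto-detected by delimiter sniffing.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Dataset, split_sample_key

log = logging.getLogger(__name__)

__all__ = ["load_dataset", "preprocess_carbon", "shannon_diversity"]


def _sniff_sep(path) -> str:
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
    except csv.Error:
        return ","


def _read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sniff_sep(path), index_col=index_col)


def load_dataset(
    design,
    functions,
    abundance: dict[str, "str | Path"],
    normalize: bool = False,
) -> Dataset:
    """Load and validate the three input tables into a Dataset.

    Taxa with zero total abundance are dropped (count logged).  With
    ``normalize=True`` each abundance column is rescaled to relative
    abundance (column sum 1), for deposited tables stored as counts.

    Raises ValueError naming the offending key on unknown mesocosms or
    time points, and on any negative abundance.
    """
    design_df = _read_table(design)
    if "mesocosm" not in design_df.columns:
        raise ValueError(f"design table {design!r} lacks a 'mesocosm' column")
    func_df = _read_table(functions)
    missing = {"mesocosm", "time", "function", "value"} - set(func_df.columns)
    if missing:
        raise ValueError(f"functions table lacks column(s) {sorted(missing)}")
    func_df["time"] = func_df["time"].astype(int)

    tables: dict[str, pd.DataFrame] = {}
    for group, path in abundance.items():
        tab = _read_table(path, index_col=0)
        tab.index.name = "taxon"
        vals = tab.to_numpy(dtype=float)
        if (vals < 0).any():
            taxon = tab.index[np.argwhere(vals < 0)[0][0]]
            raise ValueError(
                f"negative abundance for taxon {taxon!r} in group '{group}'"
            )
        empty = vals.sum(axis=1) == 0
        if empty.any():
            log.info(
                "group '%s': dropping %d taxa with zero total abundance",
                group, int(empty.sum()),
            )
            tab = tab.loc[~empty]
        if normalize:
            sums = tab.sum(axis=0)
            tab = tab.div(sums.where(sums > 0, 1.0), axis=1)
        tables[group] = tab
        log.info(
            "group '%s': %d taxa x %d samples loaded", group, *tab.shape
        )

    ds = Dataset(design=design_df, abundance=tables, functions=func_df)
    ds.validate()
    # every abundance sample must sit on the design x time grid (validate
    # checks this) and the time axes must agree across tables
    times = set(ds.times)
    for group, tab in tables.items():
        ab_times = {split_sample_key(c)[1] for c in tab.columns}
        if not ab_times <= times:
            raise ValueError(
                f"group '{group}' has time points {sorted(ab_times - times)} "
                "absent from the functions table"
            )
    log.info(
        "dataset: %d mesocosms, %d time points, %d functions",
        len(ds.mesocosms), len(ds.times), len(ds.function_names),
    )
    return ds


def preprocess_carbon(values) -> np.ndarray:
    """Shift soil d13C readings by their minimum so larger = more 13C.

    Raw d13C ratios are negative; subtracting the minimum maps the least
    enriched sample to 0 and preserves ordering.  Apply once: the shift is
    idempotent only up to the (new, zero) minimum.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if not finite.any():
        raise ValueError("preprocess_carbon: no finite values")
    return v - np.nanmin(v[finite])


def shannon_diversity(biomass) -> float:
    """Shannon H' = -sum p_i ln p_i over species with positive biomass."""
    b = np.asarray(biomass, dtype=float)
    if (b < 0).any():
        raise ValueError("biomass values must be nonnegative")
    total = b.sum()
    if total <= 0:
        raise ValueError("shannon_diversity: all-zero biomass vector")
    return float(stats.entropy(b[b > 0]))
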