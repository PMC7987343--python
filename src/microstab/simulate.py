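"""Synthetic mesocosm-experiment generator with known ground truth.

The generator emulates a sieve-gradient soil biodiversity experiment:
each mesocosm receives a random subset of a regional taxon pool whose size
shrinks along the treatment gradient, taxon abundances fluctuate
lognormally over harvests, and a planted set of "supporter" taxa raises or
lowers each ecosystem function when present.  In ``rotating`` asynchrony
mode each supporter's expected abundance peaks at the harvest it is
assigned to, so different taxa drive a function at different times.

All randomness flows from ``SimConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .config import FUNCTION_NAMES, HARVEST_INTERVAL_WEEKS, SIEVE_SIZES_UM, SimConfig
from .datatypes import Dataset, EffectEntry, EffectMap, sample_key

__all__ = [
    "generate_design",
    "generate_community",
    "assign_taxon_effects",
    "generate_functions",
    "simulate_experiment",
    "write_dataset",
]


def _sieve_sizes(n_treatments: int) -> list[int]:
    if n_treatments <= len(SIEVE_SIZES_UM):
        return list(SIEVE_SIZES_UM[:n_treatments])
    # extend the gradient geometrically above 5000 um if asked for more levels
    extra = [SIEVE_SIZES_UM[0] * 4 ** k for k in range(n_treatments - len(SIEVE_SIZES_UM), 0, -1)]
    return extra + list(SIEVE_SIZES_UM)


def generate_design(cfg: SimConfig) -> pd.DataFrame:
    """One row per mesocosm: treatment (factor + log score), origin, block.

    The numeric treatment score is log2(mesh + 1), which maps the sterile
    (0 um) level to 0 and makes the gradient log-linear; blocks are assigned
    from the replicate index, mirroring a staggered set-up order.
    """
    sieves = _sieve_sizes(cfg.n_treatments)
    rows = []
    i = 0
    for (ti, sieve), oi, ri in itertools.product(
        enumerate(sieves), range(cfg.n_origins), range(cfg.n_reps)
    ):
        i += 1
        rows.append(
            {
                "mesocosm": f"M{i:02d}",
                "treatment": f"{sieve}um",
                "treatment_order": ti,
                "sieve_um": sieve,
                "treatment_score": float(np.log2(sieve + 1)),
                "origin": f"O{oi + 1}",
                "block": f"B{ri + 1}",
                "replicate": ri + 1,
            }
        )
    design = pd.DataFrame(rows)
    design["treatment"] = pd.Categorical(
        design["treatment"],
        categories=[f"{s}um" for s in sieves],
        ordered=True,
    )
    return design


def _taxon_ids(cfg: SimConfig) -> dict[str, list[str]]:
    return {
        "fungi": [f"F{i:04d}" for i in range(1, cfg.n_taxa_fungi + 1)],
        "bacteria": [f"B{i:04d}" for i in range(1, cfg.n_taxa_bacteria + 1)],
    }


def generate_community(
    design: pd.DataFrame,
    cfg: SimConfig,
    effects: EffectMap | None = None,
) -> dict[str, pd.DataFrame]:
    """Taxa x sample abundance tables, one per organism group.

    Each mesocosm carries a random subset of the pool of size
    round(retention x pool) for its treatment, fixed across harvests;
    members get lognormal abundances per harvest and non-members zeros.
    With ``asynchrony_mode='rotating'`` and an EffectMap, each supporter's
    meanlog is boosted at its assigned harvest so its expected abundance
    peaks there.
    """
    if len(cfg.richness_retention) != cfg.n_treatments:
        raise ValueError("richness_retention length must equal n_treatments")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    pools = _taxon_ids(cfg)
    times = range(1, cfg.n_times + 1)

    peak_time: dict[str, dict[int, int]] = {}
    if effects is not None and cfg.asynchrony_mode == "rotating":
        for e in effects.entries:
            peak_time.setdefault(e.taxon, {})[e.time] = 1

    tables: dict[str, pd.DataFrame] = {}
    for group, taxa in pools.items():
        pool = len(taxa)
        cols = {}
        for _, row in design.iterrows():
            retention = cfg.richness_retention[int(row["treatment_order"])]
            k = int(round(retention * pool))
            members = rng.choice(pool, size=k, replace=False)
            member_mask = np.zeros(pool, dtype=bool)
            member_mask[members] = True
            for t in times:
                meanlog = np.full(pool, cfg.abundance_meanlog)
                for i, taxon in enumerate(taxa):
                    if t in peak_time.get(taxon, {}):
                        meanlog[i] += cfg.peak_boost
                ab = np.where(
                    member_mask,
                    rng.lognormal(meanlog, cfg.abundance_sdlog),
                    0.0,
                )
                cols[sample_key(row["mesocosm"], t)] = ab
        tables[group] = pd.DataFrame(cols, index=pd.Index(taxa, name="taxon"))
    return tables


def assign_taxon_effects(cfg: SimConfig, mode: str = "random") -> EffectMap:
    """Draw the ground-truth supporter taxa for each (function, time).

    mode='random'    independent draws per (function, time); under
                     asynchrony_mode='static' the same set is reused across
                     times within a function.
    mode='disjoint'  functions get pairwise-disjoint sets (shared across times).
    mode='identical' one set is shared by every function and time.
    Signs are +1 with probability 1 - p_negative (deterministic +1 for the
    structured modes, which exist for accumulation analytics).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    pools = _taxon_ids(cfg)
    all_taxa = pools["fungi"] + pools["bacteria"]
    n = cfg.n_supporters_per_function_time
    if n > len(all_taxa):
        raise ValueError("n_supporters_per_function_time exceeds the taxon pool")
    times = range(1, cfg.n_times + 1)
    entries: list[EffectEntry] = []

    if mode == "identical":
        chosen = rng.choice(len(all_taxa), size=n, replace=False)
        for f, t in itertools.product(FUNCTION_NAMES, times):
            entries.extend(EffectEntry(all_taxa[i], f, t, 1) for i in chosen)
    elif mode == "disjoint":
        need = n * len(FUNCTION_NAMES)
        if need > len(all_taxa):
            raise ValueError("pool too small for disjoint supporter sets")
        chosen = rng.choice(len(all_taxa), size=need, replace=False)
        for fi, f in enumerate(FUNCTION_NAMES):
            block = chosen[fi * n : (fi + 1) * n]
            for t in times:
                entries.extend(EffectEntry(all_taxa[i], f, t, 1) for i in block)
    elif mode == "random":
        for f in FUNCTION_NAMES:
            static_choice = rng.choice(len(all_taxa), size=n, replace=False)
            static_signs = np.where(rng.random(n) < cfg.p_negative, -1, 1)
            for t in times:
                if cfg.asynchrony_mode == "rotating":
                    chosen = rng.choice(len(all_taxa), size=n, replace=False)
                    signs = np.where(rng.random(n) < cfg.p_negative, -1, 1)
                else:
                    chosen, signs = static_choice, static_signs
                entries.extend(
                    EffectEntry(all_taxa[i], f, t, int(s))
                    for i, s in zip(chosen, signs)
                )
    else:
        raise ValueError(f"unknown effect-assignment mode {mode!r}")
    return EffectMap(entries)


def generate_functions(
    community: dict[str, pd.DataFrame],
    effects: EffectMap,
    cfg: SimConfig,
) -> pd.DataFrame:
    """Tidy function table: baseline + effect_size x (signed supporter count) + noise.

    A supporter contributes only where its abundance is positive at that
    (mesocosm, harvest), so treatment (via community membership) causally
    drives the functions.  ``effect_size`` and ``noise_sd`` are expressed in
    each function's ``function_scale`` units, so one scalar drives functions
    of very different magnitudes (grams of biomass vs Shannon H').
    """
    unknown = {e.function for e in effects.entries} - set(cfg.baselines)
    if unknown:
        raise ValueError(f"unknown function name(s) in effects: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    combined = pd.concat(community.values(), axis=0)
    rows = []
    for col in combined.columns:
        present = set(combined.index[combined[col].to_numpy() > 0])
        meso, t = col.rpartition("_T")[0], int(col.rpartition("_T")[2])
        for f in FUNCTION_NAMES:
            signed = sum(
                sign for taxon, sign in effects.supporters(f, t).items() if taxon in present
            )
            scale = cfg.function_scale.get(f, 1.0)
            value = (
                cfg.baselines[f]
                + scale * cfg.effect_size * signed
                + (scale * rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            )
            rows.append({"mesocosm": meso, "time": t, "function": f, "value": value})
    return pd.DataFrame(rows)


def simulate_experiment(
    cfg: SimConfig, effects_mode: str = "random"
) -> tuple[Dataset, EffectMap]:
    """Full pipeline: design -> effects -> community -> functions."""
    design = generate_design(cfg)
    effects = assign_taxon_effects(cfg, mode=effects_mode)
    community = generate_community(design, cfg, effects)
    functions = generate_functions(community, effects, cfg)
    ds = Dataset(
        design=design,
        abundance=community,
        functions=functions,
        meta={
            "seed": cfg.seed,
            "asynchrony_mode": cfg.asynchrony_mode,
            "harvest_interval_weeks": HARVEST_INTERVAL_WEEKS,
        },
    )
    ds.validate()
    return ds, effects


def write_dataset(ds: Dataset, outdir) -> dict[str, str]:
    """Write the standard input tables (design, functions, one CSV per group)."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    p = outdir / "design.csv"
    ds.design.to_csv(p, index=False)
    paths["design"] = str(p)
    p = outdir / "functions.csv"
    ds.functions.to_csv(p, index=False)
    paths["functions"] = str(p)
    for group, table in ds.abundance.items():
        p = outdir / f"abundance_{group}.csv"
        table.to_csv(p)
        paths[group] = str(p)
    return paths
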