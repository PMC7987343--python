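"""Shared containers: the experiment Dataset and the ground-truth EffectMap."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .config import FUNCTION_NAMES


def sample_key(mesocosm: str, time: int) -> str:
    """Column key for one (mesocosm, harvest) sample, e.g. ``'M01_T3'``."""
    return f"{mesocosm}_T{time}"


def split_sample_key(key: str) -> tuple[str, int]:
    mesocosm, _, t = key.rpartition("_T")
    if not mesocosm or not t.isdigit():
        raise ValueError(f"sample key {key!r} is not of the form '<mesocosm>_T<time>'")
    return mesocosm, int(t)


@dataclass(frozen=True)
class EffectEntry:
    taxon: str
    function: str
    time: int
    sign: int  # +1 or -1


@dataclass
class EffectMap:
    """Ground-truth taxon -> function effects planted by the generator.

    Each (taxon, function, time) triple appears at most once; ``sign`` says
    whether the taxon's presence raises (+1) or lowers (-1) the function.
    """

    entries: list[EffectEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [(e.taxon, e.function, e.time) for e in self.entries]
        if len(keys) != len(set(keys)):
            raise ValueError("duplicate (taxon, function, time) entry in EffectMap")
        bad = {e.function for e in self.entries} - set(FUNCTION_NAMES)
        if bad:
            raise ValueError(f"unknown function name(s) in EffectMap: {sorted(bad)}")

    def supporters(self, function: str, time: int) -> dict[str, int]:
        """taxon -> sign for one (function, time)."""
        return {
            e.taxon: e.sign
            for e in self.entries
            if e.function == function and e.time == time
        }

    def taxa(self) -> set[str]:
        return {e.taxon for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.taxon, e.function, e.time, e.sign) for e in self.entries],
            columns=["taxon", "function", "time", "sign"],
        )


@dataclass
class Dataset:
    """One loaded (or simulated) mesocosm experiment.

    design     one row per mesocosm: treatment, origin, block, replicate
    abundance  organism group -> taxa x samples table (columns are sample keys)
    functions  tidy table: mesocosm, time, function, value
    """

    design: pd.DataFrame
    abundance: dict[str, pd.DataFrame]
    functions: pd.DataFrame
    meta: dict = field(default_factory=dict)

    @property
    def mesocosms(self) -> list[str]:
        return list(self.design["mesocosm"])

    @property
    def times(self) -> list[int]:
        return sorted(self.functions["time"].unique())

    @property
    def function_names(self) -> list[str]:
        return sorted(self.functions["function"].unique())

    def validate(self) -> None:
        """Check sample-key consistency and abundance non-negativity."""
        known = set(self.design["mesocosm"])
        times = set(self.times)
        for group, table in self.abundance.items():
            for col in table.columns:
                meso, t = split_sample_key(col)
                if meso not in known:
                    raise ValueError(
                        f"abundance table '{group}' references unknown mesocosm {meso!r}"
                    )
                if t not in times:
                    raise ValueError(
                        f"abundance table '{group}' references unknown time point {t}"
                    )
            if (table.to_numpy() < 0).any():
                raise ValueError(f"negative abundance in group '{group}'")
        bad = set(self.functions["mesocosm"]) - known
        if bad:
            raise ValueError(
                f"functions table references unknown mesocosm {sorted(bad)[0]!r}"
            )
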