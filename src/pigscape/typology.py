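"""Holder typology and census summary statistics.

A *holder* (or farm) is a household keeping at least one pig.  Holders are
classified along two independent axes:

* **farming system**, from the commercial pig types kept — farrow-to-finish
  (all breeding types plus fattening pigs), nursery (all breeding types,
  no fattening), finishing (fattening only), or unclassified (any other
  combination, including native-only holders, since systems are defined on
  commercial breeds only);
* **farm scale**, from the total head count — backyard [1, 5), smallholder
  commercial [5, 50), then the large-scale classes small [50, 500),
  medium [500, 5000) and large >= 5000.  Holders under 50 head are
  smallholders; 50 head or more is large-scale farming.

The summary statistics mirror the national census breakdowns: head and
holder counts cross-tabulated by pig type / system and scale, shares of
holders and stock, pigs per holder, and compound annual growth rates for
time-series comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

PIG_TYPE_COLUMNS = ("boars", "sows", "piglets", "fattening", "native")

#: scale bins as half-open intervals on total head count
SCALE_BINS = (
    ("backyard", 1, 5),
    ("smallholder_commercial", 5, 50),
    ("small", 50, 500),
    ("medium", 500, 5000),
    ("large", 5000, np.inf),
)

SMALLHOLDER_SCALES = ("backyard", "smallholder_commercial")
LARGESCALE_SCALES = ("small", "medium", "large")
SMALLHOLDER_THRESHOLD = 50


class FarmingSystem(str, Enum):
    FARROW_TO_FINISH = "farrow_to_finish"
    NURSERY = "nursery"
    FINISHING = "finishing"
    UNCLASSIFIED = "unclassified"


class FarmScale(str, Enum):
    BACKYARD = "backyard"
    SMALLHOLDER_COMMERCIAL = "smallholder_commercial"
    SMALL = "small"
    MEDIUM = "medium"
    LARGE = "large"

    @property
    def is_smallholder(self) -> bool:
        return self.value in SMALLHOLDER_SCALES


@dataclass(frozen=True)
class HolderRecord:
    """One census holder: per-type pig counts plus sub-district membership."""

    holder_id: int
    subdistrict_id: int
    boars: int = 0
    sows: int = 0
    piglets: int = 0
    fattening: int = 0
    native: int = 0

    def __post_init__(self) -> None:
        for col in PIG_TYPE_COLUMNS:
            v = getattr(self, col)
            if v < 0 or int(v) != v:
                raise ValueError(f"{col} must be a non-negative integer, got {v}")

    @property
    def total_pigs(self) -> int:
        return int(sum(getattr(self, c) for c in PIG_TYPE_COLUMNS))


def classify_scale(total_pigs: int) -> FarmScale:
    if total_pigs < 1:
        raise ValueError("a holder must keep at least one pig")
    for name, lo, hi in SCALE_BINS:
        if lo <= total_pigs < hi:
            return FarmScale(name)
    raise AssertionError("unreachable")


def classify_system(boars: int, sows: int, piglets: int, fattening: int) -> FarmingSystem:
    breeding_complete = boars > 0 and sows > 0 and piglets > 0
    if breeding_complete and fattening > 0:
        return FarmingSystem.FARROW_TO_FINISH
    if breeding_complete:
        return FarmingSystem.NURSERY
    if fattening > 0 and boars == 0 and sows == 0 and piglets == 0:
        return FarmingSystem.FINISHING
    return FarmingSystem.UNCLASSIFIED


def classify_holder(h: HolderRecord) -> tuple[FarmingSystem, FarmScale]:
    """Farming system and farm scale of one holder.

    Native pigs count toward the scale but not toward the system (systems
    are defined on commercial pig types only).
    """
    scale = classify_scale(h.total_pigs)
    system = classify_system(h.boars, h.sows, h.piglets, h.fattening)
    return system, scale


def cagr(start_value: float, end_value: float, n_years: int) -> float:
    """Compound annual growth rate in percent.

    The constant geometric rate linking ``start_value`` to ``end_value``
    over ``n_years`` years: 100 * ((end/start)**(1/n) - 1).
    """
    if start_value <= 0 or end_value <= 0:
        raise ValueError("cagr requires positive start and end values")
    if n_years < 1:
        raise ValueError("cagr requires n_years >= 1")
    return 100.0 * ((end_value / start_value) ** (1.0 / n_years) - 1.0)


def classify_census(holders: pd.DataFrame) -> pd.DataFrame:
    """Vectorized classification of a census table.

    Adds ``total_pigs``, ``system``, ``scale`` and ``is_smallholder``
    columns to a copy of the input.
    """
    df = holders.copy()
    df["total_pigs"] = sum(df[c] for c in PIG_TYPE_COLUMNS)
    if (df["total_pigs"] < 1).any():
        raise ValueError("every holder must keep at least one pig")
    edges = [lo for _, lo, _ in SCALE_BINS] + [np.inf]
    labels = [name for name, _, _ in SCALE_BINS]
    df["scale"] = pd.cut(df["total_pigs"], bins=edges, labels=labels, right=False)
    breeding = (df["boars"] > 0) & (df["sows"] > 0) & (df["piglets"] > 0)
    fat = df["fattening"] > 0
    only_fat = fat & (df["boars"] == 0) & (df["sows"] == 0) & (df["piglets"] == 0)
    df["system"] = FarmingSystem.UNCLASSIFIED.value
    df.loc[only_fat, "system"] = FarmingSystem.FINISHING.value
    df.loc[breeding & ~fat, "system"] = FarmingSystem.NURSERY.value
    df.loc[breeding & fat, "system"] = FarmingSystem.FARROW_TO_FINISH.value
    df["is_smallholder"] = df["total_pigs"] < SMALLHOLDER_THRESHOLD
    return df


def _crosstab(df: pd.DataFrame) -> pd.DataFrame:
    """Head/holder counts per (group, scale) cell, Table-3 style.

    Pig-type rows count, per scale bin, the heads of that type and the
    holders keeping at least one pig of that type (so a multi-type holder
    appears in several rows and holder columns need not sum to 100 %).
    System rows count whole farms and all their pigs.
    """
    scales = [name for name, _, _ in SCALE_BINS]
    rows = []
    type_groups = {
        "native_pigs": df["native"],
        "breeding_pigs": df["boars"] + df["sows"] + df["piglets"],
        "fattening_pigs": df["fattening"],
    }
    all_heads = df["total_pigs"]
    for scale in scales:
        sel = df["scale"] == scale
        rows.append(("pig_types", "all_pigs", scale, int(all_heads[sel].sum()), int(sel.sum())))
        for gname, heads in type_groups.items():
            keeps = sel & (heads > 0)
            rows.append(("pig_types", gname, scale, int(heads[sel].sum()), int(keeps.sum())))
        for system in (FarmingSystem.FARROW_TO_FINISH, FarmingSystem.NURSERY, FarmingSystem.FINISHING):
            s2 = sel & (df["system"] == system.value)
            rows.append(("farming_systems", system.value, scale, int(all_heads[s2].sum()), int(s2.sum())))
    return pd.DataFrame(rows, columns=["group", "subgroup", "scale", "heads", "holders"])


def summary_from_crosstab(crosstab: pd.DataFrame) -> dict:
    """Headline statistics from a (group, subgroup, scale) head/holder table.

    Works both on cross-tabs built from holder-level data and on
    externally printed census cells with the same layout.
    """
    ct = crosstab.set_index(["group", "subgroup", "scale"])

    def cell(group, sub, scales, col):
        return int(sum(ct.loc[(group, sub, s), col] for s in scales))

    all_scales = [name for name, _, _ in SCALE_BINS]
    total_heads = cell("pig_types", "all_pigs", all_scales, "heads")
    total_holders = cell("pig_types", "all_pigs", all_scales, "holders")
    sm_holders = cell("pig_types", "all_pigs", SMALLHOLDER_SCALES, "holders")
    lf_holders = cell("pig_types", "all_pigs", LARGESCALE_SCALES, "holders")
    lf_heads = cell("pig_types", "all_pigs", LARGESCALE_SCALES, "heads")

    systems = [s.value for s in (FarmingSystem.FARROW_TO_FINISH, FarmingSystem.NURSERY, FarmingSystem.FINISHING)]
    sys_farms = {s: cell("farming_systems", s, all_scales, "holders") for s in systems}
    sys_heads = {s: cell("farming_systems", s, all_scales, "heads") for s in systems}
    n_sys_farms = sum(sys_farms.values())

    out = {
        "total_heads": total_heads,
        "total_holders": total_holders,
        "smallholder_holder_share_pct": 100.0 * sm_holders / total_holders,
        "largescale_holder_share_pct": 100.0 * lf_holders / total_holders,
        "largescale_stock_share_pct": 100.0 * lf_heads / total_heads,
        "scale_holder_share_pct": {
            name: 100.0 * cell("pig_types", "all_pigs", [name], "holders") / total_holders
            for name, _, _ in SCALE_BINS
        },
        "system_farm_share_pct": {
            s: (100.0 * sys_farms[s] / n_sys_farms if n_sys_farms else float("nan")) for s in systems
        },
        "system_pigs_per_holder": {
            s: (sys_heads[s] / sys_farms[s] if sys_farms[s] else float("nan")) for s in systems
        },
        "pig_type_heads": {
            g: cell("pig_types", g, all_scales, "heads")
            for g in ("native_pigs", "breeding_pigs", "fattening_pigs")
        },
    }
    return out


def census_summary(holders: pd.DataFrame) -> dict:
    """Cross-tabulated census summary of a holder-level table.

    Returns the cross-tab (Table-3 layout), headline share statistics and
    per-type medians of pigs per holder.
    """
    if len(holders) == 0:
        raise ValueError("census table is empty")
    df = classify_census(holders)
    ct = _crosstab(df)
    stats = summary_from_crosstab(ct)
    medians = {"all_pigs": float(df["total_pigs"].median())}
    for gname, heads in (
        ("native_pigs", df["native"]),
        ("breeding_pigs", df["boars"] + df["sows"] + df["piglets"]),
        ("fattening_pigs", df["fattening"]),
    ):
        kept = heads[heads > 0]
        medians[gname] = float(kept.median()) if len(kept) else float("nan")
    stats["median_pigs_per_holder"] = medians
    return {"crosstab": ct, "stats": stats}
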