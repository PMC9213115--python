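"""Densitometry-to-fraction arithmetic.

Western-blot band intensities of the expressed library (total, soluble, and
the thrombin-undigested portions of each) are turned into a percentage
partition of the total expressed material:

    insoluble % + soluble_degradable % + soluble_resistant % = 100

The protease-resistant component is quantified from the *undigested* band
(cleavage fragments transfer poorly and can be re-cleaved), so
soluble_resistant = soluble_uncleaved / total and soluble_degradable is the
remainder of the soluble signal. The same arithmetic applies unchanged to
post-heat-shock intensity tables.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Literal, Sequence

import numpy as np
import pandas as pd


class FractionError(ValueError):
    pass


CONDITION_COLUMNS = ["chaperone", "protease", "temperature"]
INTENSITY_COLUMNS = ["total", "soluble", "total_uncleaved", "soluble_uncleaved"]


@dataclass(frozen=True)
class FractionSummary:
    """Percentage partition of total expressed library (one replicate)."""

    insoluble: float
    soluble_degradable: float
    soluble_resistant: float
    flagged_inconsistent: bool = False

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def fraction_partition(
    total: float,
    soluble: float,
    soluble_uncleaved: float,
    total_uncleaved: float | None = None,
) -> FractionSummary:
    """Partition one replicate's intensities into percentages of total.

    Rows where soluble > total or soluble_uncleaved > soluble are physically
    inconsistent (measurement noise); they are flagged, never clipped.
    """
    if total <= 0:
        raise FractionError("total intensity must be positive")
    if min(soluble, soluble_uncleaved) < 0 or (
        total_uncleaved is not None and total_uncleaved < 0
    ):
        raise FractionError("intensities must be non-negative")
    flagged = soluble > total or soluble_uncleaved > soluble
    soluble_pct = 100.0 * soluble / total
    resistant_pct = 100.0 * soluble_uncleaved / total
    return FractionSummary(
        insoluble=100.0 - soluble_pct,
        soluble_degradable=soluble_pct - resistant_pct,
        soluble_resistant=resistant_pct,
        flagged_inconsistent=bool(flagged),
    )


def partition_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-row partitions of a densitometry table.

    Expects the intensity columns ``total, soluble, total_uncleaved,
    soluble_uncleaved``; any other columns (condition keys, replicate ids)
    are carried through.
    """
    missing = [c for c in INTENSITY_COLUMNS if c not in table.columns]
    if missing:
        raise FractionError(f"missing intensity columns: {missing}")
    parts = [
        fraction_partition(
            row.total, row.soluble, row.soluble_uncleaved, row.total_uncleaved
        ).as_dict()
        for row in table.itertuples()
    ]
    out = table.drop(columns=INTENSITY_COLUMNS).reset_index(drop=True)
    return pd.concat([out, pd.DataFrame(parts)], axis=1)


FRACTION_COLUMNS = ["insoluble", "soluble_degradable", "soluble_resistant"]


def replicate_summary(
    table: pd.DataFrame,
    group_by: Sequence[str] | None = None,
    mode: Literal["mean_of_ratios", "ratio_of_means"] = "mean_of_ratios",
) -> pd.DataFrame:
    """Mean ± sample sd of each fraction across replicates.

    ``mean_of_ratios`` (default) partitions each replicate first and averages
    the percentages; ``ratio_of_means`` averages intensities within a group
    and partitions once. Groups with fewer than 2 replicates are rejected.
    """
    if group_by is None:
        group_by = [c for c in CONDITION_COLUMNS if c in table.columns]
    if mode not in ("mean_of_ratios", "ratio_of_means"):
        raise FractionError(f"unknown mode {mode!r}")

    def summarize(group: pd.DataFrame) -> pd.Series:
        if len(group) < 2:
            raise FractionError(
                "replicate groups need >= 2 rows; check the grouping columns"
            )
        if mode == "mean_of_ratios":
            parts = partition_table(group[INTENSITY_COLUMNS])
            stats = {}
            for col in FRACTION_COLUMNS:
                stats[f"{col}_mean"] = parts[col].mean()
                stats[f"{col}_sd"] = parts[col].std(ddof=1)
            stats["n_replicates"] = len(group)
            stats["any_flagged"] = bool(parts["flagged_inconsistent"].any())
            return pd.Series(stats)
        means = group[INTENSITY_COLUMNS].mean()
        part = fraction_partition(
            means["total"], means["soluble"], means["soluble_uncleaved"],
            means["total_uncleaved"],
        )
        stats = {f"{col}_mean": getattr(part, col) for col in FRACTION_COLUMNS}
        stats.update({f"{col}_sd": np.nan for col in FRACTION_COLUMNS})
        stats["n_replicates"] = len(group)
        stats["any_flagged"] = part.flagged_inconsistent
        return pd.Series(stats)

    if not group_by:
        return summarize(table).to_frame().T
    grouped = table.groupby(list(group_by), dropna=False)
    return grouped.apply(summarize, include_groups=False).reset_index()
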