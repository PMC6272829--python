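"""Extraction-yield index and single-factor optimization summaries.

The yield index is extract weight x analyte content fraction / crude drug
weight x 100%, and the optimization compares total (four-component) yields
across levels of one factor at a time: methanol concentration, solid-liquid
ratio, extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "YieldTable",
    "YieldSummary",
    "extraction_yield",
    "yield_summary",
    "load_table1",
]

FACTORS = ("methanol_pct", "solid_liquid_ratio", "time_min")
N_COMPOUNDS = 4


@dataclass
class YieldTable:
    """Per-compound extraction yields (%) across the levels of one factor."""

    factor: str
    data: pd.DataFrame  # index: compound; columns: level (ordered)

    def __post_init__(self):
        if self.factor not in FACTORS:
            raise ValueError(f"unknown factor {self.factor!r}")
        if len(self.data.index) != N_COMPOUNDS:
            raise ValueError(f"expected {N_COMPOUNDS} compound rows")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("yields must be >= 0")

    @classmethod
    def from_long(cls, df: pd.DataFrame, factor: str) -> "YieldTable":
        sub = df[df["factor"] == factor]
        wide = sub.pivot(index="compound", columns="level", values="yield_pct")
        # preserve the level order of first appearance
        order = list(dict.fromkeys(sub["level"]))
        return cls(factor=factor, data=wide[order])


@dataclass
class YieldSummary:
    factor: str
    level_sums: dict[str, float]  # total yield (4 components) per level
    best_level: str | None
    degenerate: bool = False      # all-zero table: no best level, no change

    def relative_change(self, level_a: str, level_b: str) -> float:
        """Percent change in total yield from level_a to level_b."""
        a = self.level_sums[level_a]
        b = self.level_sums[level_b]
        if a == 0:
            raise ValueError(
                f"total yield at {level_a!r} is zero; relative change undefined"
            )
        return (b - a) / a * 100.0


def extraction_yield(
    extract_weight: float, content_fraction: float, crude_weight: float
) -> float:
    """Extraction yield (%) = extract weight x content / crude weight x 100."""
    if crude_weight <= 0:
        raise ValueError("crude drug weight must be positive")
    return extract_weight * content_fraction / crude_weight * 100.0


def yield_summary(table: YieldTable) -> YieldSummary:
    """Column sums over the four components, best level, degenerate flag."""
    sums = {
        str(level): round(float(table.data[level].sum()), 10)
        for level in table.data.columns
    }
    if all(v == 0 for v in sums.values()):
        return YieldSummary(table.factor, sums, None, degenerate=True)
    best = max(sums, key=lambda k: sums[k])
    return YieldSummary(table.factor, sums, best)


def load_table1(path: str | Path | None = None) -> dict[str, YieldTable]:
    """The shipped single-factor optimization tables, one per factor."""
    if path is None:
        path = Path(resources.files("pmqc.data").joinpath("table1_yields.tsv"))  # type: ignore[arg-type]
    df = pd.read_csv(path, sep="\t")
    return {f: YieldTable.from_long(df, f) for f in FACTORS}
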