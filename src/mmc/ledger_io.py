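"""Feed/biomass accounting and comparative arithmetic.

Cumulative feed totals are exact compensated sums (``math.fsum``); the
percentage helpers return unrounded values, with integer rounding applied only
at the reporting layer (the convention used when quoting savings or yield
gains, e.g. "saved ~18% nitrate").
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "FeedLedger",
    "YieldRecord",
    "savings_percent",
    "percent_increase",
    "average_feed_rate",
]


@dataclass
class FeedLedger:
    """Per-interval feed records with exact cumulative totals."""

    entries: list[tuple[float, str, float]] = field(default_factory=list)  # (t, nutrient, mg/L)
    initial_charges: dict[str, float] = field(default_factory=dict)

    def add_feed(self, time_h: float, nutrient: str, mass_mg_L: float) -> None:
        if mass_mg_L < 0:
            raise ValueError("feed mass cannot be negative")
        self.entries.append((time_h, nutrient, mass_mg_L))

    def fed_total(self, nutrient: str) -> float:
        """Sum of feeds only, excluding the initial charge."""
        return math.fsum(m for _, n, m in self.entries if n == nutrient)

    def cumulative(self, nutrient: str, include_initial: bool = True) -> float:
        """Total supply; ``include_initial`` resolves the with/without-charge ambiguity."""
        total = self.fed_total(nutrient)
        if include_initial:
            total = math.fsum([total, self.initial_charges.get(nutrient, 0.0)])
        return total

    def nutrients(self) -> list[str]:
        return sorted({n for _, n, _ in self.entries} | set(self.initial_charges))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["time_h", "nutrient", "feed_mg_L"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_schedule_csv(cls, path, initial_charges: dict[str, float] | None = None):
        df = pd.read_csv(path)
        ledger = cls(initial_charges=dict(initial_charges or {}))
        for _, row in df.iterrows():
            ledger.add_feed(float(row["time_h"]), str(row["nutrient"]), float(row["feed_mg_L"]))
        return ledger


@dataclass
class YieldRecord:
    """Biomass and product yields for one condition at one time point."""

    condition: str
    time_h: float
    biomass_mg_L: float
    yields_mg_L: dict[str, float] = field(default_factory=dict)  # FAME, lutein, ...
    contents_pct_dw: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.biomass_mg_L < 0:
            raise ValueError("biomass cannot be negative")
        for tag, table in (("yield", self.yields_mg_L), ("content", self.contents_pct_dw)):
            for name, v in table.items():
                if v < 0:
                    raise ValueError(f"negative {tag} for {name}")
        for name, pct in self.contents_pct_dw.items():
            if name in self.yields_mg_L and self.biomass_mg_L > 0:
                implied = pct * self.biomass_mg_L / 100.0
                if abs(implied - self.yields_mg_L[name]) > 0.01 * max(
                    1.0, self.yields_mg_L[name]
                ):
                    raise ValueError(
                        f"{name}: content {pct}% of {self.biomass_mg_L} mg/L implies "
                        f"{implied:.2f} mg/L, recorded yield is {self.yields_mg_L[name]}"
                    )


def savings_percent(reference_total: float, mmc_total: float) -> float:
    """Percent of the reference supply saved: 100·(ref − mmc)/ref, unrounded."""
    if reference_total <= 0:
        raise ValueError("reference total must be positive")
    return 100.0 * (reference_total - mmc_total) / reference_total


def percent_increase(base: float, new: float) -> float:
    """Percent increase from base to new: 100·(new − base)/base, unrounded."""
    if base <= 0:
        raise ValueError("base must be positive")
    return 100.0 * (new - base) / base


def average_feed_rate(
    ledger: FeedLedger, nutrient: str, t_start: float, t_end: float
) -> float:
    """Mean feeding rate over a window, mg·L⁻¹·h⁻¹ (feeds only, no initial charge)."""
    if t_end <= t_start:
        raise ValueError("empty window: t_end must exceed t_start")
    fed = math.fsum(
        m for t, n, m in ledger.entries if n == nutrient and t_start < t <= t_end
    )
    return fed / (t_end - t_start)
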