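"""Community composition arithmetic: relative abundances, guild panels,
incubation shifts and clone-library percentages.

The default methanotroph guild panel holds the five aerobic methanotroph
genera recovered from these soils (Methylosinus, Methylocaldum,
Methylobacter, Methylomicrobium, Crenothrix); ANME archaea are tracked by
a separate single-genus panel.  A day-0 -> day-90 change is reported both
ways the field states it: percentage-point change (final minus initial)
and fold change (final over initial) — e.g. a genus moving from 2.35% to
35.25% of the guild "increased by 32.9 percentage points (15-fold)".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd

__all__ = [
    "TaxonCountTable",
    "GuildPanel",
    "ShiftMetric",
    "METHANOTROPH_PANEL",
    "ANME_PANEL",
    "relative_abundance",
    "guild_composition",
    "abundance_shift",
    "clone_percentages",
    "dominant_taxon",
    "round_half_up",
]


def round_half_up(value: float, decimals: int = 2) -> float:
    """Decimal half-up rounding (display convention for percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class GuildPanel:
    guild_name: str
    member_taxa: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_taxa:
            raise ValueError("a guild panel must have at least one member")
        object.__setattr__(
            self, "member_taxa", frozenset(t.lower() for t in self.member_taxa)
        )

    def matches(self, taxon: str) -> bool:
        return taxon.lower() in self.member_taxa


METHANOTROPH_PANEL = GuildPanel(
    "aerobic_methanotrophs",
    frozenset(
        {
            "Methylosinus",
            "Methylocaldum",
            "Methylobacter",
            "Methylomicrobium",
            "Crenothrix",
        }
    ),
)
ANME_PANEL = GuildPanel("anme", frozenset({"Candidatus Methanoperedens"}))


class TaxonCountTable:
    """Samples x taxa count matrix with per-sample metadata.

    ``counts`` is a dataframe indexed by sample id with one column per
    taxon (genus level expected); ``meta`` carries depth_label and
    timepoint per sample.  Counts must be non-negative with a positive
    total per sample, and taxon names unique.
    """

    def __init__(self, counts: pd.DataFrame, meta: pd.DataFrame | None = None):
        if counts.columns.duplicated().any():
            raise ValueError("taxon names must be unique")
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        totals = counts.sum(axis=1)
        if (totals <= 0).any():
            bad = totals.index[totals <= 0].tolist()
            raise ValueError(f"samples with zero total counts: {bad}")
        self.counts = counts
        self.meta = meta if meta is not None else pd.DataFrame(index=counts.index)

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "TaxonCountTable":
        """Build from a long table with sample_id, taxon, count columns
        (depth_label / timepoint carried into metadata when present)."""
        wide = (
            table.pivot_table(
                index="sample_id", columns="taxon", values="count",
                aggfunc="sum", fill_value=0,
            )
            .sort_index()
        )
        meta_cols = [c for c in ("depth_label", "timepoint") if c in table.columns]
        meta = (
            table.groupby("sample_id")[meta_cols].first().loc[wide.index]
            if meta_cols
            else None
        )
        return cls(wide, meta)


@dataclass(frozen=True)
class ShiftMetric:
    taxon: str
    ra_initial_pct: float
    ra_final_pct: float
    pp_change: float
    fold_change: float  # NaN when the baseline is zero


def relative_abundance(table: TaxonCountTable) -> pd.DataFrame:
    """Per-sample percentages; each row sums to 100."""
    totals = table.counts.sum(axis=1)
    return table.counts.div(totals, axis=0) * 100.0


def guild_composition(table: TaxonCountTable, panel: GuildPanel) -> pd.DataFrame:
    """Within-guild percentages over panel members only (sum to 100).

    Genus names are matched case-insensitively.  Samples with no panel
    counts get NaN rows (flagged empty guild) rather than an error.
    """
    members = [c for c in table.counts.columns if panel.matches(str(c))]
    if not members:
        raise ValueError(
            f"no members of panel {panel.guild_name!r} present in the table"
        )
    sub = table.counts[members]
    totals = sub.sum(axis=1)
    out = sub.div(totals.where(totals > 0), axis=0) * 100.0
    return out


def abundance_shift(ra_initial_pct: float, ra_final_pct: float, taxon: str = "") -> ShiftMetric:
    """Percentage-point and fold change between two relative abundances."""
    for name, v in (("ra_initial_pct", ra_initial_pct), ("ra_final_pct", ra_final_pct)):
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
    pp = ra_final_pct - ra_initial_pct
    fold = ra_final_pct / ra_initial_pct if ra_initial_pct > 0 else math.nan
    return ShiftMetric(
        taxon=taxon,
        ra_initial_pct=float(ra_initial_pct),
        ra_final_pct=float(ra_final_pct),
        pp_change=pp,
        fold_change=fold,
    )


def clone_percentages(counts: Mapping[str, int]) -> dict[str, float]:
    """Clone-library percentages, half-up rounded to 2 decimals.

    The raw ratios are recoverable as count/total; the returned mapping
    is the display form.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("clone library is empty")
    if any(c < 0 for c in counts.values()):
        raise ValueError("clone counts must be non-negative")
    return {
        taxon: round_half_up(100.0 * c / total, 2) for taxon, c in counts.items()
    }


def dominant_taxon(percent_row: Mapping[str, float] | pd.Series) -> str:
    """Taxon with the maximal percentage; ties break alphabetically."""
    items = (
        percent_row.items() if isinstance(percent_row, pd.Series) else percent_row.items()
    )
    pairs = [(str(t), float(v)) for t, v in items if not math.isnan(float(v))]
    if not pairs:
        raise ValueError("empty percentage row")
    return min(pairs, key=lambda tv: (-tv[1], tv[0]))[0]
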