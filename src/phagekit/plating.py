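"""Phage titration from spot dilution series and efficiency of plating (EOP).

A stock is diluted 10-fold serially and a fixed volume of each dilution is
spotted on a bacterial lawn.  The titer is read from the most dilute spot
with a countable number of plaques:

    titer [PFU/mL] = count / spot_volume * 10^exponent

EOP expresses a phage's titer on each strain as a percentage of its titer on
the most permissive strain:

    EOP_s = 100 * titer_s / max_strain titer
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

DEFAULT_SPOT_VOLUME_ML = 0.01  # 10 uL spots
DEFAULT_COUNTABLE_MIN = 3
DEFAULT_COUNTABLE_MAX = 100


@dataclass
class SpotSeries:
    """Plaque counts across a 10-fold dilution series."""

    dilution_exponents: list[int]
    plaque_counts: list[int]
    spot_volume: float = DEFAULT_SPOT_VOLUME_ML

    def __post_init__(self):
        if len(self.dilution_exponents) != len(self.plaque_counts):
            raise ValueError("exponents and counts must have equal length")
        if any(b <= a for a, b in zip(self.dilution_exponents, self.dilution_exponents[1:])):
            raise ValueError("dilution exponents must be strictly increasing")
        if any(c < 0 for c in self.plaque_counts):
            raise ValueError("plaque counts must be non-negative")
        if self.spot_volume <= 0:
            raise ValueError("spot volume must be positive")


@dataclass
class EopTable:
    rows: list[dict]  # strain_id, titer, eop_percent
    reference_strain: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def titer_from_spots(
    series: SpotSeries,
    countable_min: int = DEFAULT_COUNTABLE_MIN,
    countable_max: int = DEFAULT_COUNTABLE_MAX,
) -> float:
    """Titer from the most dilute countable spot.

    The most dilute spot whose count lies in [countable_min, countable_max]
    is used, minimizing plaque-overlap bias at lower dilutions.
    """
    for exp, count in zip(reversed(series.dilution_exponents), reversed(series.plaque_counts)):
        if countable_min <= count <= countable_max:
            return count / series.spot_volume * 10**exp
    raise ValueError(
        f"series uncountable: no spot with {countable_min}-{countable_max} plaques"
    )


def efficiency_of_plating(titers: list[tuple[str, float]]) -> EopTable:
    """EOP per strain, relative to the strain of maximal titer (= 100%).

    Ties for the reference broken by input order.
    """
    if not titers:
        raise ValueError("no titers supplied")
    if any(t < 0 for _, t in titers):
        raise ValueError("titers must be non-negative")
    max_titer = max(t for _, t in titers)
    if max_titer == 0:
        raise ValueError("all titers are zero")
    reference = next(s for s, t in titers if t == max_titer)
    rows = [
        {"strain_id": s, "titer": t, "eop_percent": 100.0 * t / max_titer}
        for s, t in titers
    ]
    return EopTable(rows=rows, reference_strain=reference)


def read_titer_tsv(path: str | Path) -> list[tuple[str, float]]:
    """Read (strain, pfu_per_ml) TSV into a titer list."""
    df = pd.read_csv(path, sep="\t")
    if not {"strain", "pfu_per_ml"}.issubset(df.columns):
        raise ValueError("titer TSV must have columns strain, pfu_per_ml")
    return [(str(r.strain), float(r.pfu_per_ml)) for r in df.itertuples()]


def read_spot_tsv(path: str | Path, spot_volume: float = DEFAULT_SPOT_VOLUME_ML) -> dict[str, SpotSeries]:
    """Read (strain, dilution_exponent, plaque_count) TSV into per-strain series."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "dilution_exponent", "plaque_count"}
    if not required.issubset(df.columns):
        raise ValueError(f"spot TSV must have columns {sorted(required)}")
    out = {}
    for strain, grp in df.groupby("strain", sort=False):
        grp = grp.sort_values("dilution_exponent")
        out[str(strain)] = SpotSeries(
            dilution_exponents=[int(x) for x in grp["dilution_exponent"]],
            plaque_counts=[int(x) for x in grp["plaque_count"]],
            spot_volume=spot_volume,
        )
    return out


def format_eop_percent(value: float) -> str:
    """Two-significant-figure percentage, matching conventional reporting."""
    if value == 0:
        return "0"
    from decimal import Decimal

    d = Decimal(value)
    return f"{float(f'{d:.2g}'):g}"
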