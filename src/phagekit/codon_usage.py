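"""Codon-usage statistics: counts, relative frequencies f_i, phage:host
ratios r_i, three-bin classification, and GC content.

The central comparison is, per codon i,

    f_i = (count of codon i) / (total codons counted),
    r_i = f_i(phage) / f_i(host),

with r_i >= 1.1 binned "higher" (phage over-uses the codon), 0.9 <= r_i < 1.1
"similar", and r_i < 0.9 "lower".  Codons the host never uses have an
undefined ratio and are excluded from rankings.  Start codons are removed
before counting; stop codons are counted by default.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .sequence_io import CdsSet

CODONS: tuple[str, ...] = tuple(
    "".join(p) for p in itertools.product("ACGT", repeat=3)
)

# standard genetic code, DNA alphabet; stops marked "*"
CODON_TO_AA: dict[str, str] = {c: str(Seq(c).translate()) for c in CODONS}

BIN_HIGHER = "higher"
BIN_SIMILAR = "similar"
BIN_LOWER = "lower"
BIN_UNDEFINED = "undefined"

DEFAULT_LO = 0.9
DEFAULT_HI = 1.1


@dataclass
class CodonCountTable:
    counts: dict[str, int]

    def __post_init__(self):
        full = {c: 0 for c in CODONS}
        full.update(self.counts)
        if set(full) != set(CODONS):
            extra = set(self.counts) - set(CODONS)
            raise ValueError(f"non-codon keys in count table: {sorted(extra)}")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CodonFrequencyProfile:
    f: dict[str, float]


@dataclass
class CodonRatioTable:
    r: dict[str, float | None]  # None = undefined (host frequency zero)
    bin: dict[str, str]
    thresholds: tuple[float, float] = (DEFAULT_LO, DEFAULT_HI)

    def defined(self) -> dict[str, float]:
        return {c: v for c, v in self.r.items() if v is not None}


def strip_start_codons(cds: CdsSet) -> CdsSet:
    """Remove the first codon of every CDS (the start codon)."""
    out = []
    for fid, seq in cds.cds_list:
        if len(seq) < 6:
            raise ValueError(f"CDS {fid} shorter than 6 nt; stripping would leave <1 codon")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {fid} length {len(seq)} not divisible by 3")
        out.append((fid, seq[3:]))
    return CdsSet(genome_id=cds.genome_id, cds_list=out)


def count_codons(cds: CdsSet) -> CodonCountTable:
    """Pool non-overlapping in-frame codon counts across all CDS in the set."""
    if len(cds) == 0:
        raise ValueError("no valid CDS")
    counts = {c: 0 for c in CODONS}
    for fid, seq in cds.cds_list:
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS {fid} length {len(seq)} not divisible by 3")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if codon not in counts:
                raise ValueError(f"CDS {fid}: non-ACGT codon {codon!r} at position {i + 1}")
            counts[codon] += 1
    return CodonCountTable(counts=counts)


def relative_frequencies(counts: CodonCountTable) -> CodonFrequencyProfile:
    """f_i = count_i / total for each of the 64 codons."""
    total = counts.total
    if total == 0:
        raise ValueError("cannot compute frequencies from an empty count table")
    return CodonFrequencyProfile(f={c: counts.counts[c] / total for c in CODONS})


def classify_ratio(r: float, lo: float = DEFAULT_LO, hi: float = DEFAULT_HI) -> str:
    """Bin a ratio: higher iff r >= hi; similar iff lo <= r < hi; lower iff r < lo."""
    if r < 0:
        raise ValueError(f"ratio must be non-negative, got {r}")
    if r >= hi:
        return BIN_HIGHER
    if r >= lo:
        return BIN_SIMILAR
    return BIN_LOWER


def usage_ratio(
    phage: CodonFrequencyProfile,
    host: CodonFrequencyProfile,
    lo: float = DEFAULT_LO,
    hi: float = DEFAULT_HI,
) -> CodonRatioTable:
    """r_i = f_i(phage) / f_i(host); host-zero codons flagged undefined."""
    r: dict[str, float | None] = {}
    bins: dict[str, str] = {}
    for c in CODONS:
        fh = host.f[c]
        if fh == 0:
            r[c] = None
            bins[c] = BIN_UNDEFINED
        else:
            val = phage.f[c] / fh
            r[c] = val
            bins[c] = classify_ratio(val, lo, hi)
    return CodonRatioTable(r=r, bin=bins, thresholds=(lo, hi))


def top_bottom_codons(
    ratios: CodonRatioTable, k: int = 10
) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """The k largest and k smallest defined ratios.

    Ties broken by codon lexicographic order; top list descending by ratio,
    bottom list ascending.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    defined = ratios.defined()
    if len(defined) < k:
        raise ValueError(f"only {len(defined)} defined ratios, need k={k}")
    top = sorted(defined.items(), key=lambda cv: (-cv[1], cv[0]))[:k]
    bottom = sorted(defined.items(), key=lambda cv: (cv[1], cv[0]))[:k]
    return top, bottom


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); ambiguity characters ignored entirely."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    at = seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / (gc + at)


def ratio_table_frame(
    phage_counts: CodonCountTable,
    host_counts: CodonCountTable,
    ratios: CodonRatioTable,
) -> pd.DataFrame:
    """Tidy per-codon table: counts, frequencies, ratio, bin, amino acid."""
    phage_f = relative_frequencies(phage_counts)
    host_f = relative_frequencies(host_counts)
    rows = []
    for c in CODONS:
        rows.append(
            {
                "codon": c,
                "amino_acid": CODON_TO_AA[c],
                "count_phage": phage_counts.counts[c],
                "count_host": host_counts.counts[c],
                "f_phage": phage_f.f[c],
                "f_host": host_f.f[c],
                "ratio": ratios.r[c],
                "bin": ratios.bin[c],
            }
        )
    return pd.DataFrame(rows)


def write_ratio_report(
    frame: pd.DataFrame,
    ratios: CodonRatioTable,
    out_dir: str | Path,
    k: int = 10,
) -> dict:
    """Write the codon TSV plus a JSON report with thresholds and top/bottom-k."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(out_dir / "codon_usage.tsv", sep="\t", index=False)
    top, bottom = top_bottom_codons(ratios, k)
    report = {
        "thresholds": {"lo": ratios.thresholds[0], "hi": ratios.thresholds[1]},
        "top": [{"codon": c, "ratio": v} for c, v in top],
        "bottom": [{"codon": c, "ratio": v} for c, v in bottom],
        "n_undefined": sum(1 for b in ratios.bin.values() if b == BIN_UNDEFINED),
    }
    with open(out_dir / "top_bottom.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
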