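"""Cross-reference over-represented phage codons against the phage's tRNA
anticodon complement.

A phage that over-uses codons its host reads poorly may carry its own tRNAs
for them; this module asks, for each codon whose usage ratio exceeds a
threshold, whether a cognate anticodon exists among the phage's predicted
tRNAs.  Anticodons are handled in the DNA alphabet, written 5'->3', so the
exact cognate of a codon is its reverse complement.  Optional wobble rules
relax the third-position pairing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .codon_usage import CodonRatioTable
from .sequence_io import reverse_complement

# Wobble rules: codon third-position bases readable by an anticodon whose
# 5' (position-34) base is the key.  DNA alphabet.  "G:U" pairing lets G34
# read codon-3 T as well as C, and T34 (U34) read G as well as A; an
# inosine-like A34 reads T, C and A.  Exact Watson-Crick is always included.
WOBBLE_RULES: dict[str, set[str]] = {
    "A": {"T", "C", "A"},  # inosine-like reading
    "C": {"G"},
    "G": {"C", "T"},
    "T": {"A", "G"},
}


@dataclass
class AnticodonSet:
    """Predicted tRNA anticodons: (anticodon 5'->3' DNA triplet, amino acid)."""

    entries: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self):
        for ac, _aa in self.entries:
            if len(ac) != 3 or any(c not in "ACGT" for c in ac):
                raise ValueError(f"invalid anticodon {ac!r}: must be an ACGT triplet")

    def anticodons(self) -> list[str]:
        return [ac for ac, _ in self.entries]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AnticodonSet":
        """Read a two-column TSV (anticodon, amino_acid); header optional."""
        entries = []
        with open(path) as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                ac = row[0].strip().upper().replace("U", "T")
                if ac.lower() in ("anticodon",):
                    continue
                aa = row[1].strip() if len(row) > 1 else "?"
                entries.append((ac, aa))
        return cls(entries=entries)


@dataclass
class AdaptationReport:
    """Per over-represented codon: its ratio and whether a cognate tRNA exists."""

    rows: list[dict]
    threshold_used: float

    def codons_without_trna(self) -> list[str]:
        return [r["codon"] for r in self.rows if not r["has_cognate_trna"]]

    def to_records(self) -> list[dict]:
        return [dict(r) for r in self.rows]


def codon_to_anticodon(codon: str) -> str:
    """Exact cognate anticodon (reverse complement), reported 5'->3'."""
    if len(codon) != 3 or any(c not in "ACGT" for c in codon):
        raise ValueError(f"invalid codon {codon!r}: must be an ACGT triplet")
    return reverse_complement(codon)


def _anticodon_reads_codon(anticodon: str, codon: str, wobble: bool) -> bool:
    if not wobble:
        return anticodon == codon_to_anticodon(codon)
    # positions 2,3 of the anticodon pair Watson-Crick with codon 2,1
    exact = codon_to_anticodon(codon)
    if anticodon[1:] != exact[1:]:
        return False
    return codon[2] in WOBBLE_RULES.get(anticodon[0], set())


def match_overrepresented(
    ratios: CodonRatioTable,
    trnas: AnticodonSet,
    min_ratio: float = 1.1,
    wobble: bool = False,
) -> AdaptationReport:
    """Report, for each defined codon with r_i >= min_ratio, whether the
    anticodon set contains a cognate tRNA.

    With wobble disabled, cognate means the exact reverse complement; with
    wobble enabled, third-position pairings in WOBBLE_RULES also count.
    An empty anticodon set yields has_cognate_trna = False everywhere.
    """
    if min_ratio <= 0:
        raise ValueError("min_ratio must be positive")
    rows = []
    for codon, r in sorted(ratios.defined().items(), key=lambda cv: (-cv[1], cv[0])):
        if r < min_ratio:
            continue
        matched = [ac for ac in trnas.anticodons() if _anticodon_reads_codon(ac, codon, wobble)]
        rows.append(
            {
                "codon": codon,
                "ratio": r,
                "has_cognate_trna": bool(matched),
                "matched_anticodons": matched,
            }
        )
    return AdaptationReport(rows=rows, threshold_used=min_ratio)
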