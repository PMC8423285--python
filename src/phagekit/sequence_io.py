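"""Genome and annotation I/O: FASTA records, GFF3 CDS features, CDS extraction.

Coordinates are GFF3-style (1-based, inclusive) at the interface and converted
to 0-based half-open Python slices internally.  Minus-strand coding sequences
are returned reverse-complemented, i.e. always in the reading orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# IUPAC nucleotide codes accepted on ingest; codon counting later restricts to ACGT.
IUPAC_DNA = set("ACGTNRYSWKMBDHV")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC codes supported)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """A single genome (or contig) sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsFeature:
    """A CDS annotation on a genome.

    ``parts`` holds the (start, end) pairs of a multi-segment CDS sharing one
    ID, in ascending coordinate order; single-segment features have one part.
    ``start``/``end`` are the envelope of all parts.
    """

    seq_id: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    feature_id: str
    phase: int = 0
    parts: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.feature_id}: strand must be + or -, got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"feature {self.feature_id}: start {self.start} > end {self.end}")
        if not self.parts:
            object.__setattr__(self, "parts", ((self.start, self.end),))

    @property
    def span(self) -> int:
        return sum(e - s + 1 for s, e in self.parts)


@dataclass
class CdsSet:
    """Ordered collection of validated coding sequences from one genome."""

    genome_id: str
    cds_list: list[tuple[str, str]]  # (feature_id, nucleotide string)

    def __len__(self) -> int:
        return len(self.cds_list)

    def sequences(self) -> list[str]:
        return [s for _, s in self.cds_list]

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.cds_list)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for fid, seq in self.cds_list:
                fh.write(f">{fid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class ValidationPolicy:
    """Which CDS survive extraction.

    drop_internal_stop: discard CDS with an in-frame stop before the last codon.
    drop_ambiguous: discard CDS containing non-ACGT characters.
    drop_partial: discard features whose annotated phase is nonzero (partial CDS).
    keep_final_stop: retain the terminal codon even if it is a stop.
    """

    drop_internal_stop: bool = True
    drop_ambiguous: bool = True
    drop_partial: bool = True
    keep_final_stop: bool = True
    min_length: int = 6


def read_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a (multi-record) FASTA file into GenomeRecords.

    Sequences are upper-cased and internal whitespace is removed.  Raises
    ValueError on an empty file or on characters outside the IUPAC DNA set.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "").replace("\t", "")
        for pos, ch in enumerate(seq):
            if ch not in IUPAC_DNA:
                raise ValueError(
                    f"record {rec.id}: non-nucleotide character {ch!r} at position {pos + 1}"
                )
        records.append(GenomeRecord(id=rec.id, sequence=seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def _parse_gff_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for item in attr_field.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff_cds(path: str | Path, seq_id_filter: str | None = None) -> list[CdsFeature]:
    """Read CDS rows from a GFF3 file.

    Rows of other feature types are ignored.  Rows sharing an ID attribute are
    joined into one multi-part feature (parts kept in ascending coordinate
    order; extraction handles strand).  Returns features in file order of
    first appearance.
    """
    raw: dict[str, dict] = {}
    order: list[str] = []
    anon = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, phase_s, attr_s = fields
            if ftype != "CDS":
                continue
            if seq_id_filter is not None and seqid != seq_id_filter:
                continue
            start, end = int(start_s), int(end_s)
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -, got {strand!r}")
            attrs = _parse_gff_attributes(attr_s)
            fid = attrs.get("ID")
            if fid is None:
                anon += 1
                fid = f"cds_{anon}"
            phase = int(phase_s) if phase_s in ("0", "1", "2") else 0
            key = (seqid, fid)
            if key not in raw:
                raw[key] = {"seqid": seqid, "strand": strand, "phase": phase, "parts": []}
                order.append(key)
            elif raw[key]["strand"] != strand:
                raise ValueError(f"{path}:{lineno}: segments of {fid} disagree on strand")
            raw[key]["parts"].append((start, end))

    features = []
    for key in order:
        seqid, fid = key
        info = raw[key]
        parts = tuple(sorted(info["parts"]))
        features.append(
            CdsFeature(
                seq_id=seqid,
                start=parts[0][0],
                end=parts[-1][1],
                strand=info["strand"],
                feature_id=fid,
                phase=info["phase"],
                parts=parts,
            )
        )
    return features


def _splice(genome: GenomeRecord, feature: CdsFeature) -> str:
    """Concatenate the feature's parts in reading order."""
    slices = [genome.sequence[s - 1 : e] for s, e in feature.parts]
    if feature.strand == "+":
        return "".join(slices)
    # minus strand: slices taken in descending coordinate order, each revcomp'd
    return "".join(reverse_complement(s) for s in reversed(slices))


def extract_cds(
    genome: GenomeRecord,
    features: Sequence[CdsFeature],
    policy: ValidationPolicy | None = None,
) -> CdsSet:
    """Extract strand-resolved coding sequences, dropping invalid ones.

    Drops (with a log line ``DROPPED <id> <reason>``) sequences whose length is
    not a multiple of 3, that carry internal in-frame stops or ambiguity codes
    (policy-dependent), or are annotated as partial.  Raises on out-of-bounds
    features and when no CDS survives.
    """
    policy = policy or ValidationPolicy()
    kept: list[tuple[str, str]] = []
    for feat in features:
        if feat.seq_id != genome.id:
            raise ValueError(f"feature {feat.feature_id} is on {feat.seq_id}, not genome {genome.id}")
        if feat.start < 1 or feat.end > genome.length:
            raise ValueError(
                f"feature {feat.feature_id} ({feat.start}..{feat.end}) out of bounds "
                f"for genome {genome.id} of length {genome.length}"
            )
        if policy.drop_partial and feat.phase != 0:
            logger.info("DROPPED %s partial (phase=%d)", feat.feature_id, feat.phase)
            continue
        seq = _splice(genome, feat)
        if len(seq) % 3 != 0:
            logger.info("DROPPED %s length %d not divisible by 3", feat.feature_id, len(seq))
            continue
        if len(seq) < policy.min_length:
            logger.info("DROPPED %s shorter than %d", feat.feature_id, policy.min_length)
            continue
        if policy.drop_ambiguous and any(c not in "ACGT" for c in seq):
            logger.info("DROPPED %s contains ambiguity codes", feat.feature_id)
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if policy.drop_internal_stop and any(c in STOP_CODONS for c in codons[:-1]):
            logger.info("DROPPED %s internal stop codon", feat.feature_id)
            continue
        if not policy.keep_final_stop and codons[-1] in STOP_CODONS:
            seq = seq[:-3]
            if len(seq) < policy.min_length:
                logger.info("DROPPED %s too short after stop removal", feat.feature_id)
                continue
        kept.append((feat.feature_id, seq))
    if not kept:
        raise ValueError(f"no valid CDS extracted from genome {genome.id}")
    return CdsSet(genome_id=genome.id, cds_list=kept)


def write_fasta(records: Iterable[GenomeRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")
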