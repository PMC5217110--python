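"""Shared readers and writers: FASTA, GFF3, TSV expression tables.

Coordinates are stored 0-based half-open internally and converted to/from
the 1-based inclusive convention of GFF3 at the file boundary. Gene ids are
treated as opaque strings throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

logger = logging.getLogger("teiscope")

NA = "NA"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G/C among unambiguous bases; 0.0 for empty input."""
    seq = seq.upper()
    n = sum(1 for b in seq if b in "ACGT")
    if n == 0:
        return 0.0
    return sum(1 for b in seq if b in "GC") / n


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} dict."""
    seqs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        seqs[name] = "".join(chunks)
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences wrapped to `width` columns."""
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models

Interval = tuple[int, int]  # 0-based half-open


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_length(intervals: Iterable[Interval]) -> int:
    return sum(e - s for s, e in intervals)


@dataclass
class Transcript:
    """One isoform: genomic feature intervals, all 0-based half-open."""

    transcript_id: str
    exons: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        exons = sorted(self.exons)
        return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


@dataclass
class GeneModel:
    """A gene with one or more isoforms on a chromosome."""

    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def representative(self) -> Transcript:
        """Representative model: the first mRNA."""
        return self.transcripts[0]

    def span(self) -> Interval:
        spans = [t.span() for t in self.transcripts]
        return (min(s for s, _ in spans), max(e for _, e in spans))

    def midpoint(self) -> int:
        s, e = self.span()
        return (s + e) // 2


def extract_sequence(genome: dict[str, str], chrom: str, intervals: Iterable[Interval], strand: str) -> str:
    """Splice genomic intervals into a transcript-orientation sequence.

    Intervals are concatenated in genomic order and the result is
    reverse-complemented for minus-strand features.
    """
    seq = "".join(genome[chrom][s:e] for s, e in sorted(intervals))
    return revcomp(seq) if strand == "-" else seq


# ---------------------------------------------------------------------------
# GFF3

_FEATURE_MAP = {
    "five_prime_UTR": "utr5",
    "CDS": "cds",
    "three_prime_UTR": "utr3",
    "exon": "exons",
}


class Gff3ParseError(ValueError):
    pass


def _parse_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k] = v
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file with gene/mRNA/UTR/CDS/exon features into gene models.

    Coordinates are converted from 1-based inclusive to 0-based half-open.
    Raises Gff3ParseError with the offending line number on missing parent
    links or out-of-range coordinates.
    """
    genes: dict[str, GeneModel] = {}
    tx_parent: dict[str, str] = {}
    tx: dict[str, Transcript] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise Gff3ParseError(f"line {lineno}: expected 9 columns, got {len(fields)}")
            chrom, _, ftype, start, end, _, strand, _, attr_text = fields
            start_i, end_i = int(start) - 1, int(end)  # -> 0-based half-open
            if start_i < 0 or end_i <= start_i:
                raise Gff3ParseError(f"line {lineno}: bad coordinates {start}..{end}")
            attrs = _parse_attributes(attr_text)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise Gff3ParseError(f"line {lineno}: gene without ID")
                genes[gid] = GeneModel(gene_id=gid, chrom=chrom, strand=strand)
            elif ftype == "mRNA":
                tid, parent = attrs.get("ID"), attrs.get("Parent")
                if tid is None or parent is None:
                    raise Gff3ParseError(f"line {lineno}: mRNA missing ID/Parent")
                if parent not in genes:
                    raise Gff3ParseError(f"line {lineno}: mRNA parent {parent} not seen")
                t = Transcript(transcript_id=tid)
                tx[tid] = t
                tx_parent[tid] = parent
                genes[parent].transcripts.append(t)
            elif ftype in _FEATURE_MAP:
                parent = attrs.get("Parent")
                if parent is None or parent not in tx:
                    raise Gff3ParseError(f"line {lineno}: {ftype} parent {parent} not seen")
                getattr(tx[parent], _FEATURE_MAP[ftype]).append((start_i, end_i))
    for t in tx.values():
        t.exons.sort()
        t.utr5.sort()
        t.cds.sort()
        t.utr3.sort()
        if not t.exons:
            # exon rows optional; reconstruct the exon chain from typed pieces
            t.exons = merge_intervals(t.utr5 + t.cds + t.utr3)
    return list(genes.values())


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span()
            fh.write(
                f"{g.chrom}\tteiscope\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for t in g.transcripts:
                ts, te = t.span()
                fh.write(
                    f"{g.chrom}\tteiscope\tmRNA\t{ts + 1}\t{te}\t.\t{g.strand}\t.\t"
                    f"ID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for ftype, key in (
                    ("exon", "exons"),
                    ("five_prime_UTR", "utr5"),
                    ("CDS", "cds"),
                    ("three_prime_UTR", "utr3"),
                ):
                    for s, e in getattr(t, key):
                        fh.write(
                            f"{g.chrom}\tteiscope\t{ftype}\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                            f"Parent={t.transcript_id}\n"
                        )


# ---------------------------------------------------------------------------
# TSV tables


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA], keep_default_na=False)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA)
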