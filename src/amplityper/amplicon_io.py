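"""Readers, writers and barcode-aware demultiplexing for amplicon data.

The pipeline's external formats are deliberately minimal: FASTQ (Sanger
Phred+33) in, FASTA out, and a three-column TSV for genotype tables
(``individual_id<TAB>method<TAB>alleles`` with comma-separated allele
names; ``#`` comment lines allowed).

Demultiplexing follows the library design used for single-end Ion Torrent
amplicon runs: each read begins with (optionally an adapter,) a
sample-specific barcode, a short linker and the forward PCR primer. A read
is assigned to the unique sample whose expected prefix matches its 5' end
within a configurable mismatch tolerance; ambiguous matches are never
assigned. Only adapter+barcode+linker are trimmed on assignment — the
forward primer is kept so that downstream length filtering operates on the
primer-inclusive amplicon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Read",
    "BarcodeScheme",
    "Amplicon",
    "FastqParseError",
    "read_fastq",
    "write_fastq",
    "write_fasta",
    "read_fasta",
    "demultiplex",
    "DemuxResult",
    "read_genotype_table",
    "write_genotype_table",
]

GENOTYPE_COLUMNS = ("individual_id", "method", "alleles")

# HL030 / HL032: the DRB exon 2 primer pair bracketing the 236 bp insert
FORWARD_PRIMER = "ATCCTCTCTCTGCAGCACATTTCC"
REVERSE_PRIMER = "TCGCCGCTGCACAGTGAAACTCTC"


class FastqParseError(ValueError):
    """Raised for malformed FASTQ records; names the failing record index."""


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, nucleotides and per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.qualities)} quality values "
                f"for {len(self.sequence)} bases"
            )
        if self.qualities and min(self.qualities) < 0:
            raise ValueError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mean_quality(self) -> float:
        return sum(self.qualities) / len(self.qualities)


@dataclass(frozen=True)
class BarcodeScheme:
    """Expected 5' read structure: adapter? + barcode + linker + forward primer.

    ``adapter`` participates in matching only when ``match_adapter`` is set;
    the Ion Torrent A adapter is normally removed by the instrument.
    """

    sample_barcodes: dict[str, str]
    forward_primer: str
    reverse_primer: str
    linker: str = "GAT"
    adapter: str = ""
    match_adapter: bool = False

    def __post_init__(self) -> None:
        if not self.forward_primer or not self.reverse_primer:
            raise ValueError("primers must be non-empty")
        if not self.sample_barcodes:
            raise ValueError("at least one sample barcode required")
        barcodes = list(self.sample_barcodes.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("sample barcodes must be unique")

    def expected_prefix(self, sample_id: str) -> str:
        """Full matched prefix for a sample (adapter only if configured)."""
        head = self.adapter if self.match_adapter else ""
        return head + self.sample_barcodes[sample_id] + self.linker + self.forward_primer

    def trim_length(self, sample_id: str) -> int:
        """Bases removed on assignment: adapter?+barcode+linker, primer kept."""
        head = len(self.adapter) if self.match_adapter else 0
        return head + len(self.sample_barcodes[sample_id]) + len(self.linker)


@dataclass
class Amplicon:
    """All reads attributed to one individual at one locus, with provenance."""

    sample_id: str
    reads: list[Read] = field(default_factory=list)
    provenance: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def depth(self) -> int:
        return len(self.reads)

    def record(self, stage: str, count: int) -> None:
        if count < 0:
            raise ValueError("provenance counters are non-negative")
        self.provenance[stage] = count


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream reads from a Sanger (Phred+33) FASTQ file.

    Malformed records (sequence/quality length mismatch, truncated block)
    raise :class:`FastqParseError` naming the 1-based record index.
    """
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            index += 1
            try:
                title, sequence, quality = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqParseError(f"FASTQ record {index}: {exc}") from exc
            qualities = tuple(ord(c) - 33 for c in quality)
            if any(q < 0 for q in qualities):
                raise FastqParseError(
                    f"FASTQ record {index}: quality character below '!' — "
                    "only Phred+33 encoding is supported"
                )
            try:
                yield Read(title.split()[0], sequence.upper(), qualities)
            except ValueError as exc:
                raise FastqParseError(f"FASTQ record {index}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ (inverse of :func:`read_fastq`)."""
    with open(path, "w") as handle:
        for read in reads:
            quality = "".join(chr(q + 33) for q in read.qualities)
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n{quality}\n")


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (name, sequence) pairs as FASTA in the given order.

    Duplicate names are rejected: allele registries must stay bijective.
    """
    names = [name for name, _ in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate FASTA record names: {dupes}")
    with open(path, "w") as handle:
        for name, sequence in records:
            handle.write(f">{name}\n{sequence}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ordered (name, sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _mismatches(observed: str, expected: str, limit: int) -> int:
    """Hamming mismatches between a read prefix and the expected prefix.

    Early-exits once the limit is exceeded; a short read counts the missing
    tail as mismatches.
    """
    if len(observed) < len(expected):
        return limit + 1
    count = 0
    for a, b in zip(observed, expected):
        if a != b:
            count += 1
            if count > limit:
                return count
    return count


@dataclass
class DemuxResult:
    """Demultiplexing output: per-sample amplicons plus rejection accounting."""

    amplicons: dict[str, Amplicon]
    unassigned: int
    ambiguous: int
    total: int

    @property
    def assigned(self) -> int:
        return sum(len(a) for a in self.amplicons.values())


def demultiplex(
    reads: Iterable[Read],
    scheme: BarcodeScheme,
    tolerance: int = 0,
) -> DemuxResult:
    """Assign reads to samples by their 5' barcode structure.

    A read is assigned to sample ``s`` iff its prefix matches
    ``adapter? + barcode(s) + linker + forward_primer`` with at most
    ``tolerance`` mismatches, and no other sample also matches. Ambiguous
    reads (two samples within tolerance) are counted separately and never
    assigned. On assignment the adapter/barcode/linker part is trimmed;
    the forward primer is retained.
    """
    if not 0 <= tolerance <= 2:
        raise ValueError("barcode mismatch tolerance must be 0..2")
    prefixes = {s: scheme.expected_prefix(s) for s in scheme.sample_barcodes}
    amplicons = {s: Amplicon(sample_id=s) for s in scheme.sample_barcodes}
    unassigned = ambiguous = total = 0
    for read in reads:
        total += 1
        hits = [s for s, p in prefixes.items() if _mismatches(read.sequence, p, tolerance) <= tolerance]
        if len(hits) == 1:
            sample = hits[0]
            cut = scheme.trim_length(sample)
            trimmed = Read(read.read_id, read.sequence[cut:], read.qualities[cut:])
            amplicons[sample].reads.append(trimmed)
        elif len(hits) > 1:
            ambiguous += 1
            unassigned += 1
        else:
            unassigned += 1
    for amp in amplicons.values():
        amp.record("demux_seen", total)
        amp.record("demux_assigned", len(amp))
    return DemuxResult(amplicons=amplicons, unassigned=unassigned, ambiguous=ambiguous, total=total)


def _parse_alleles(cell: str) -> tuple[str, ...]:
    alleles = tuple(a.strip() for a in str(cell).split(",") if a.strip())
    return alleles


def read_genotype_table(path: str | Path) -> pd.DataFrame:
    """Read a genotype TSV into a DataFrame with an ``alleles`` tuple column.

    Columns: individual_id, method, alleles (comma-separated names). At most
    one row per (individual, method). The reader does not enforce the
    two-allele biology — a three-allele row is accepted here and flagged
    downstream by the calling layer.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        names=list(GENOTYPE_COLUMNS),
        header=None,
        dtype=str,
        skip_blank_lines=True,
    )
    # tolerate a literal header row
    if not frame.empty and tuple(frame.iloc[0]) == GENOTYPE_COLUMNS:
        frame = frame.iloc[1:].reset_index(drop=True)
    dupes = frame.duplicated(subset=["individual_id", "method"])
    if dupes.any():
        bad = frame.loc[dupes, ["individual_id", "method"]].iloc[0].tolist()
        raise ValueError(f"duplicate (individual, method) row: {bad}")
    frame["alleles"] = frame["alleles"].map(_parse_alleles)
    return frame.reset_index(drop=True)


def write_genotype_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a genotype DataFrame back to the three-column TSV dialect."""
    dupes = table.duplicated(subset=["individual_id", "method"])
    if dupes.any():
        raise ValueError("duplicate (individual, method) rows")
    with open(path, "w") as handle:
        handle.write("# individual_id\tmethod\talleles\n")
        for row in table.itertuples(index=False):
            alleles = ",".join(row.alleles)
            handle.write(f"{row.individual_id}\t{row.method}\t{alleles}\n")


def genotype_table(rows: Iterable[tuple[str, str, Sequence[str]]]) -> pd.DataFrame:
    """Build a genotype DataFrame from (individual, method, alleles) triples."""
    frame = pd.DataFrame(
        [(i, m, tuple(a)) for i, m, a in rows], columns=list(GENOTYPE_COLUMNS)
    )
    if frame.duplicated(subset=["individual_id", "method"]).any():
        raise ValueError("duplicate (individual, method) rows")
    return frame
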