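"""Pre-screening utilities: KrakenUniq-style report filtering and read
preprocessing.

The depth proxy is the number of reads assigned directly to a taxon
(taxReads); the breadth proxy is the number of unique reference k-mers
covered. Defaults (200 reads, 1000 unique k-mers, species rank) follow the
thresholds used for candidate selection in ancient-metagenomics screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

__all__ = [
    "KrakenReportRow",
    "FilterConfig",
    "KmerParams",
    "ReportParseError",
    "parse_krakenuniq_report",
    "write_krakenuniq_report",
    "filter_candidates",
    "write_candidates",
    "kmers_per_read",
    "count_unique_kmers_covered",
    "filter_reads_by_length",
    "trim_adapter",
]

REPORT_HEADER = "%\treads\ttaxReads\tkmers\tdup\tcov\ttaxID\trank\ttaxName"


class ReportParseError(ValueError):
    """Raised when a report line cannot be parsed; names the line number."""


@dataclass
class KrakenReportRow:
    """One taxon line of a KrakenUniq report (9 tab-separated columns)."""

    pct: float
    reads: int
    tax_reads: int
    kmers: int
    dup: float
    cov: float
    taxid: int
    rank: str
    tax_name: str  # indentation preserved

    def to_line(self) -> str:
        return (f"{self.pct:g}\t{self.reads}\t{self.tax_reads}\t{self.kmers}\t"
                f"{self.dup:g}\t{self.cov:g}\t{self.taxid}\t{self.rank}\t"
                f"{self.tax_name}")


@dataclass(frozen=True)
class FilterConfig:
    """Candidate filter: inclusive thresholds on taxReads (depth proxy) and
    unique k-mers (breadth proxy), restricted to the given ranks.

    ``rank_keep`` defaults to species only; add "sequence"/"no rank" when
    strain-level assemblies would otherwise be missed.
    """

    min_unique_kmers: int = 1000
    min_tax_reads: int = 200
    rank_keep: frozenset[str] = frozenset({"species"})

    def __post_init__(self):
        if self.min_unique_kmers < 0 or self.min_tax_reads < 0:
            raise ValueError("thresholds must be >= 0")
        object.__setattr__(self, "rank_keep", frozenset(self.rank_keep))


@dataclass(frozen=True)
class KmerParams:
    """k-mer window bookkeeping for reads of length L at k-mer size k."""

    k: int = 31
    L: int = 50

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > self.L:
            raise ValueError(f"k ({self.k}) must not exceed read length L ({self.L})")


def parse_krakenuniq_report(path) -> list[KrakenReportRow]:
    """Read a KrakenUniq-dialect report (columns: %, reads, taxReads, kmers,
    dup, cov, taxID, rank, taxName). Lines starting with '#' or '%' are
    headers/comments."""
    rows: list[KrakenReportRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "%")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise ReportParseError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append(KrakenReportRow(
                    pct=float(parts[0]), reads=int(parts[1]),
                    tax_reads=int(parts[2]), kmers=int(parts[3]),
                    dup=float(parts[4]), cov=float(parts[5]),
                    taxid=int(parts[6]), rank=parts[7], tax_name=parts[8],
                ))
            except ValueError as exc:
                raise ReportParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_krakenuniq_report(rows: Iterable[KrakenReportRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(REPORT_HEADER + "\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def filter_candidates(rows: Iterable[KrakenReportRow],
                      config: FilterConfig | None = None) -> list[KrakenReportRow]:
    """Keep rows at a retained rank with taxReads ≥ min_tax_reads and
    kmers ≥ min_unique_kmers (inclusive); input order preserved."""
    config = config or FilterConfig()
    return [
        r for r in rows
        if r.rank in config.rank_keep
        and r.tax_reads >= config.min_tax_reads
        and r.kmers >= config.min_unique_kmers
    ]


def write_candidates(rows: Iterable[KrakenReportRow], path) -> None:
    """Candidate list TSV (taxID, taxName, taxReads, kmers) — the artifact's
    stand-in for dynamic alignment-database building."""
    with open(path, "w") as fh:
        fh.write("taxID\ttaxName\ttaxReads\tkmers\n")
        for r in rows:
            fh.write(f"{r.taxid}\t{r.tax_name.strip()}\t{r.tax_reads}\t{r.kmers}\n")


def kmers_per_read(params: KmerParams) -> int:
    """Number of k-mer windows in a read: L − k + 1."""
    return params.L - params.k + 1


def count_unique_kmers_covered(alignments, reference: str, k: int = 31) -> int:
    """Number of distinct reference k-mers whose window lies fully inside at
    least one aligned read span.

    Overlapping or abutting read spans merge into contiguous covered
    stretches, so reads tiling the whole reference recover every reference
    k-mer. For isolated (non-adjacent) reads on a reference whose k-mers
    are all distinct the count is additive: Σ over reads of
    (read length − k + 1) — the arithmetic behind the 1000-unique-k-mer
    default (50 reads × 20 windows).
    """
    ref_len = len(reference)
    spans: list[tuple[int, int]] = []
    for aln in alignments:
        start = aln.pos
        end = start + len(aln.read_seq)
        if start < 0 or end > ref_len:
            raise ValueError(
                f"alignment {getattr(aln, 'read_id', '?')} spans [{start}, {end}) "
                f"outside reference of length {ref_len}"
            )
        spans.append((start, end))
    spans.sort()
    merged: list[list[int]] = []
    for start, end in spans:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    kmers = {reference[s:s + k]
             for start, end in merged
             for s in range(start, end - k + 1)}
    return len(kmers)


def filter_reads_by_length(reads: Iterable[SeqRecord],
                           min_len: int = 31) -> Iterator[SeqRecord]:
    """Yield only reads strictly longer than min_len (default keeps > 31 bp,
    the k-mer taxonomic-specificity floor)."""
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    for rec in reads:
        if len(rec) > min_len:
            yield rec


def trim_adapter(read: SeqRecord, adapter: str, min_overlap: int = 3) -> SeqRecord:
    """Remove a 3′ adapter occurrence (and everything after it).

    A position qualifies when the read matches an adapter prefix of at least
    ``min_overlap`` bases exactly, either as a full internal occurrence or as
    a suffix overlap running off the 3′ end. The rightmost-starting
    qualifying match is trimmed; qualities are sliced in lockstep.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = str(read.seq)
    n = len(seq)
    for s in range(n - min_overlap, -1, -1):
        m = min(len(adapter), n - s)
        if seq[s:s + m] == adapter[:m]:
            return read[:s]
    return read
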