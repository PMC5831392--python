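"""Raw-read cleaning, accounting, length distribution and genome mapping.

Raw small-RNA reads carry the 3' sequencing adapter downstream of the
~19-24 nt insert.  Cleaning assigns every read to exactly one category by
a fixed first-failing-test cascade:

    1. ``no_3_adapter``          no 3' adapter found in the read
    2. ``insert_null``           empty insert (adapter starts at position 0)
    3. ``adapter5_contaminant``  insert begins with the 5' adapter
    4. ``short_lt18``            trimmed insert shorter than ``min_len``
    5. ``polyA``                 insert is >= 70% adenine
    6. clean

The cascade order mirrors the order in which sequencing reports
conventionally tabulate these removals, and the per-category tallies plus
the clean-read total form an exact partition of the input
(`AccountingReport` enforces the integer identity).

The raw-to-high-quality step (base-calling QC) happens upstream of any
FASTQ file; the input here is treated as high-quality reads.

Genome mapping is exact substring search of each collapsed unique read
against both strands; miRNA quantification downstream requires perfect
matches, so mismatch-tolerant alignment would only add reads that are
discarded later anyway.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

from .thermo import revcomp_dna

#: Internal category keys, in cascade (and report) order.
CATEGORIES: tuple[str, ...] = (
    "no_3_adapter",
    "insert_null",
    "adapter5_contaminant",
    "short_lt18",
    "polyA",
)

#: Human-readable report row labels per category.
CATEGORY_LABELS: dict[str, str] = {
    "no_3_adapter": "3' adapter null",
    "insert_null": "Insert null",
    "adapter5_contaminant": "5' adapter contaminants",
    "short_lt18": "Smaller than 18 nt",
    "polyA": "PolyA",
}

DEFAULT_POLYA_FRACTION = 0.7


@dataclass
class CleanReadSet:
    """Collapsed clean reads: unique insert sequence -> read count."""

    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def write_fasta(self, path: str | Path) -> None:
        """Write collapsed reads as FASTA with ``seq_N_xCOUNT`` headers."""
        with open(path, "w") as fh:
            for i, (seq, count) in enumerate(
                sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0])), start=1
            ):
                fh.write(f">seq_{i}_x{count}\n{seq}\n")

    @classmethod
    def read_fasta(cls, path: str | Path) -> "CleanReadSet":
        counts: dict[str, int] = {}
        header = None
        seq_parts: list[str] = []

        def flush() -> None:
            if header is None:
                return
            count = int(header.rsplit("_x", 1)[1])
            counts["".join(seq_parts)] = counts.get("".join(seq_parts), 0) + count

        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    flush()
                    header = line[1:]
                    seq_parts = []
                elif line:
                    seq_parts.append(line)
            flush()
        return cls(counts)


@dataclass
class AccountingReport:
    """Per-library read accounting mirroring a sequencing summary table."""

    raw_reads: int
    high_quality_reads: int
    removed: dict[str, int]
    clean_reads: int
    clean_percent: float
    mapped_reads: int | None = None
    mapped_percent: float | None = None

    @classmethod
    def from_tallies(
        cls,
        high_quality_reads: int,
        removed: Mapping[str, int],
        raw_reads: int | None = None,
        mapped_reads: int | None = None,
    ) -> "AccountingReport":
        """Build a report from removal tallies; derived fields computed.

        ``clean_reads = high_quality - sum(removed)`` as an exact integer
        identity; percentages are reported to 2 decimals (round half to
        even).
        """
        removed = {c: int(removed.get(c, 0)) for c in CATEGORIES}
        clean = int(high_quality_reads) - sum(removed.values())
        report = cls(
            raw_reads=int(raw_reads) if raw_reads is not None else int(high_quality_reads),
            high_quality_reads=int(high_quality_reads),
            removed=removed,
            clean_reads=clean,
            clean_percent=round(100.0 * clean / high_quality_reads, 2),
        )
        if mapped_reads is not None:
            report.mapped_reads = int(mapped_reads)
            report.mapped_percent = round(100.0 * mapped_reads / clean, 2)
        return report

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("Raw reads", self.raw_reads, None),
            ("High quality reads", self.high_quality_reads, 100.0),
        ]
        for cat in CATEGORIES:
            rows.append(
                (
                    CATEGORY_LABELS[cat],
                    self.removed[cat],
                    round(100.0 * self.removed[cat] / self.high_quality_reads, 2),
                )
            )
        rows.append(("Clean reads", self.clean_reads, self.clean_percent))
        if self.mapped_reads is not None:
            rows.append(("Mapping on genome", self.mapped_reads, self.mapped_percent))
        return pd.DataFrame(rows, columns=["category", "total", "percent"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def find_adapter(
    seq: str, adapter: str, min_overlap: int = 6, max_mismatch: int = 1
) -> int | None:
    """Locate the 3' adapter in a read.

    Returns the start index of the longest adapter prefix (>= min_overlap
    bases, <= max_mismatch mismatches) found in the read, preferring the
    longest prefix and then the leftmost occurrence; None if absent.
    """
    n = len(seq)
    for length in range(min(len(adapter), n), min_overlap - 1, -1):
        prefix = adapter[:length]
        for pos in range(0, n - length + 1):
            mismatches = 0
            for a, b in zip(seq[pos : pos + length], prefix):
                if a != b:
                    mismatches += 1
                    if mismatches > max_mismatch:
                        break
            else:
                return pos
    return None


def classify_read(
    seq: str,
    adapter3: str,
    adapter5: str,
    min_len: int = 18,
    polya_fraction: float = DEFAULT_POLYA_FRACTION,
) -> tuple[str, str | None]:
    """Assign a read to one cascade category.

    Returns ``(category, insert)`` where category is one of CATEGORIES or
    ``"clean"``; insert is the adapter-trimmed sequence (None when the 3'
    adapter is absent).
    """
    seq = seq.upper()
    idx = find_adapter(seq, adapter3.upper())
    if idx is None:
        return "no_3_adapter", None
    insert = seq[:idx]
    if not insert:
        return "insert_null", insert
    overlap = min(len(insert), len(adapter5))
    if overlap >= 6:
        mismatches = sum(a != b for a, b in zip(insert[:overlap], adapter5[:overlap]))
        if mismatches <= 1:
            return "adapter5_contaminant", insert
    if len(insert) < min_len:
        return "short_lt18", insert
    if insert.count("A") / len(insert) >= polya_fraction:
        return "polyA", insert
    return "clean", insert


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTQ file.

    Aborts with the 1-based record number on a malformed record.
    """
    with open(path) as fh:
        record = 0
        while True:
            header = fh.readline()
            if not header:
                return
            record += 1
            seq = fh.readline().rstrip("\n")
            plus = fh.readline()
            qual = fh.readline().rstrip("\n")
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or not qual
                or len(seq) != len(qual)
            ):
                raise ValueError(f"malformed FASTQ record {record} in {path}")
            yield header[1:].split()[0], seq.upper()


def filter_reads(
    reads: Iterable[tuple[str, str]],
    adapter3: str,
    adapter5: str,
    min_len: int = 18,
    polya_fraction: float = DEFAULT_POLYA_FRACTION,
) -> tuple[CleanReadSet, AccountingReport]:
    """Run the filter cascade over a read stream.

    Reads are collapsed to unique sequences before classification, so the
    tallies are independent of input order by construction.
    """
    if not adapter3 or not adapter5:
        raise ValueError("adapters must be non-empty")
    seq_counts: collections.Counter[str] = collections.Counter()
    for _rid, seq in reads:
        seq_counts[seq.upper()] += 1

    removed = {c: 0 for c in CATEGORIES}
    clean_counts: dict[str, int] = {}
    total = 0
    for seq, count in seq_counts.items():
        total += count
        category, insert = classify_read(seq, adapter3, adapter5, min_len, polya_fraction)
        if category == "clean":
            clean_counts[insert] = clean_counts.get(insert, 0) + count
        else:
            removed[category] += count

    clean = CleanReadSet(dict(sorted(clean_counts.items())))
    report = AccountingReport.from_tallies(total, removed)
    assert report.clean_reads == clean.total
    return clean, report


def length_distribution(clean: CleanReadSet) -> dict[int, tuple[int, float]]:
    """Read-length histogram of clean reads as ``length -> (count, percent)``."""
    if clean.total == 0:
        raise ValueError("clean read set is empty")
    by_len: collections.Counter[int] = collections.Counter()
    for seq, count in clean.counts.items():
        by_len[len(seq)] += count
    total = clean.total
    return {
        length: (count, 100.0 * count / total)
        for length, count in sorted(by_len.items())
    }


def map_reads(
    clean: CleanReadSet, genome: Mapping[str, str]
) -> tuple[pd.DataFrame, pd.Series, int]:
    """Map collapsed clean reads to a genome by exact substring search.

    A read maps if it occurs exactly (0 mismatches) on either strand.
    Multi-mappers are recorded at every locus but each read is counted
    once in the mapped total.

    Returns
    -------
    (assignments, per_chromosome, mapped_reads):
        assignments: one row per (read sequence, locus) with 1-based
        inclusive coordinates on the forward strand and the read count;
        per_chromosome: reads per chromosome (multi-mappers contribute to
        each chromosome they hit); mapped_reads: total count of reads with
        at least one hit.
    """
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    genome_upper = {c: s.upper() for c, s in genome.items()}
    rows = []
    mapped_total = 0
    chrom_tally: collections.Counter[str] = collections.Counter()
    for seq, count in clean.counts.items():
        hits = []
        rc = revcomp_dna(seq)
        for chrom, chrom_seq in genome_upper.items():
            for query, strand in ((seq, "+"), (rc, "-")):
                start = chrom_seq.find(query)
                while start != -1:
                    hits.append((chrom, strand, start + 1, start + len(seq)))
                    start = chrom_seq.find(query, start + 1)
        if hits:
            mapped_total += count
            for chrom in {h[0] for h in hits}:
                chrom_tally[chrom] += count
            for chrom, strand, start, end in hits:
                rows.append((seq, count, chrom, strand, start, end))
    assignments = pd.DataFrame(
        rows, columns=["seq", "count", "chrom", "strand", "start", "end"]
    )
    per_chrom = pd.Series(dict(chrom_tally), dtype="int64").sort_index()
    return assignments, per_chrom, mapped_total
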