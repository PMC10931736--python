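"""Sequencing-read quality filtering.

A read is removed if it (in this precedence) contains the adapter sequence,
has N content strictly above 10%, or is low quality — bases with Phred
quality <= 20 making up strictly more than 50% of the read. Each read is
counted in exactly one QC-report bucket, so the report always partitions
the input: n_input = n_kept + n_adapter + n_highN + n_lowq.

Thresholds are strict inequalities; a read with exactly 10% N or exactly
50% low-quality bases is kept. Reads are judged independently (single-read
semantics), so filtering is order-independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Iterator, TextIO

from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "QCReport",
    "has_high_n",
    "is_low_quality",
    "classify_read",
    "filter_reads",
    "read_fastq",
    "write_fastq",
]


@dataclass(frozen=True)
class ReadRecord:
    """One FASTQ read: identifier, bases over {A,C,G,T,N}, per-base Phred scores."""

    id: str
    bases: str
    quals: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases vs {len(self.quals)} quality scores"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class QCReport:
    """Counts of kept and removed reads; buckets partition the input."""

    n_input: int = 0
    n_kept: int = 0
    n_adapter: int = 0
    n_highN: int = 0
    n_lowq: int = 0

    def check(self) -> None:
        if self.n_input != self.n_kept + self.n_adapter + self.n_highN + self.n_lowq:
            raise AssertionError("QC report buckets do not partition the input")

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    def __str__(self) -> str:
        kept_pct = 100.0 * self.n_kept / self.n_input if self.n_input else 0.0
        return (
            f"reads in: {self.n_input}; kept: {self.n_kept} ({kept_pct:.1f}%); "
            f"removed: adapter {self.n_adapter}, high-N {self.n_highN}, "
            f"low-quality {self.n_lowq}"
        )


def has_high_n(read: ReadRecord, threshold: float = 0.10) -> bool:
    """True iff the N fraction strictly exceeds ``threshold``; empty reads are False."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    if len(read) == 0:
        return False
    return read.bases.count("N") / len(read) > threshold


def is_low_quality(read: ReadRecord, q_cut: int = 20, frac_cut: float = 0.5) -> bool:
    """True iff bases with quality <= q_cut make up strictly more than
    frac_cut of the read; empty reads are False."""
    if len(read) == 0:
        return False
    n_low = sum(1 for q in read.quals if q <= q_cut)
    return n_low / len(read) > frac_cut


def classify_read(
    read: ReadRecord,
    adapter: str,
    n_threshold: float = 0.10,
    q_cut: int = 20,
    frac_cut: float = 0.5,
) -> str:
    """Label one read: 'adapter' | 'highN' | 'lowQ' | 'clean' (that precedence)."""
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if adapter in read.bases:
        return "adapter"
    if has_high_n(read, n_threshold):
        return "highN"
    if is_low_quality(read, q_cut, frac_cut):
        return "lowQ"
    return "clean"


def filter_reads(
    reads: Iterable[ReadRecord],
    adapter: str,
    n_threshold: float = 0.10,
    q_cut: int = 20,
    frac_cut: float = 0.5,
) -> tuple[list[ReadRecord], QCReport]:
    """Remove adapter-containing, high-N and low-quality reads.

    Returns the kept reads and a QCReport whose buckets partition the input.
    """
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.n_input += 1
        label = classify_read(read, adapter, n_threshold, q_cut, frac_cut)
        if label == "clean":
            kept.append(read)
            report.n_kept += 1
        elif label == "adapter":
            report.n_adapter += 1
        elif label == "highN":
            report.n_highN += 1
        else:
            report.n_lowq += 1
    report.check()
    return kept, report


def read_fastq(path) -> Iterator[ReadRecord]:
    """Parse a Phred+33 FASTQ file; a malformed record raises with its index."""
    i = -1
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            yield ReadRecord(rec.id, str(rec.seq), tuple(rec.letter_annotations["phred_quality"]))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record near index {i + 1}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], handle_or_path) -> int:
    """Write 4-line Phred+33 FASTQ; returns the number of records written."""
    own = isinstance(handle_or_path, (str, bytes)) or hasattr(handle_or_path, "__fspath__")
    fh: TextIO = open(handle_or_path, "w") if own else handle_or_path
    n = 0
    try:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    finally:
        if own:
            fh.close()
    return n
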