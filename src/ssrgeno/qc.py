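"""Read quality control: 3'-end quality trimming and a length filter.

The pipeline's first stage removes low-confidence base calls before any
locus assignment.  Bases with Phred score below the threshold (default 30)
are trimmed from the 3' end — scanning from the last base toward the 5'
end and stopping at the first base at or above the threshold — and reads
shorter than the minimum length (default 75 bp) after trimming are
discarded.  An optional strict mode instead drops any read containing a
single sub-threshold base anywhere.

Internal low-quality bases are retained by default: the downstream anchor
matching tolerates isolated mismatches, and dropping whole reads for one
bad interior call would waste depth.
"""

from __future__ import annotations

import dataclasses
import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

DEFAULT_MIN_QUAL = 30
DEFAULT_MIN_LEN = 75

#: FASTQ quality encoding offset (Sanger / Illumina 1.8+).
PHRED_OFFSET = 33


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with per-base Phred qualities."""

    read_id: str
    seq: str
    quals: tuple[int, ...]
    sample_id: str = ""

    def __post_init__(self):
        if len(self.seq) != len(self.quals):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.seq)} != "
                f"quality length {len(self.quals)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclasses.dataclass(frozen=True)
class QCParams:
    min_qual: int = DEFAULT_MIN_QUAL
    min_len: int = DEFAULT_MIN_LEN
    strict_mode: bool = False

    def __post_init__(self):
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclasses.dataclass
class QCReport:
    reads_in: int = 0
    reads_out: int = 0
    bases_trimmed: int = 0
    malformed: int = 0

    @property
    def pass_fraction(self) -> float:
        return self.reads_out / self.reads_in if self.reads_in else 0.0

    def to_dict(self) -> dict:
        return {
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "bases_trimmed": self.bases_trimmed,
            "malformed": self.malformed,
            "pass_fraction": self.pass_fraction,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def trim_read(read: ReadRecord, params: QCParams) -> ReadRecord:
    """Trim sub-threshold bases from the 3' end.

    Scans from the last base toward the 5' end and cuts at the first base
    with quality >= ``min_qual``; the 5' end is never touched.  May return
    an empty read when every base fails.
    """
    end = len(read)
    q = read.quals
    while end > 0 and q[end - 1] < params.min_qual:
        end -= 1
    if end == len(read):
        return read
    return ReadRecord(read.read_id, read.seq[:end], read.quals[:end], read.sample_id)


def filter_reads(
    reads: Iterable[ReadRecord], params: QCParams = QCParams()
) -> tuple[list[ReadRecord], QCReport]:
    """Trim each read, then drop those shorter than ``min_len``.

    Order is preserved.  In strict mode a read containing any base below
    ``min_qual`` is dropped outright (no trimming).
    """
    report = QCReport()
    kept: list[ReadRecord] = []
    for read in reads:
        report.reads_in += 1
        if params.strict_mode:
            if any(q < params.min_qual for q in read.quals):
                continue
            trimmed = read
        else:
            trimmed = trim_read(read, params)
            report.bases_trimmed += len(read) - len(trimmed)
        if len(trimmed) >= params.min_len:
            kept.append(trimmed)
            report.reads_out += 1
    return kept, report


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def parse_fastq(path: str | Path, sample_id: str = "") -> Iterator[ReadRecord]:
    """Iterate a FASTQ file (optionally gzipped) as ReadRecords.

    Phred+33 quality encoding is assumed.  Malformed records abort the
    parse with a ValueError carrying the file name (Biopython's parser is
    strict about 4-line structure).
    """
    with _open_maybe_gzip(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield ReadRecord(
                read_id=title.split()[0],
                seq=seq.upper(),
                quals=tuple(ord(c) - PHRED_OFFSET for c in qual),
                sample_id=sample_id,
            )


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    """Write reads as 4-line Phred+33 FASTQ (gzipped iff path ends .gz)."""
    n = 0
    with _open_maybe_gzip(path, "wt") as fh:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            fh.write(f"@{read.read_id}\n{read.seq}\n+\n{qual}\n")
            n += 1
    return n


def filter_fastq(
    in_path: str | Path,
    out_path: str | Path,
    params: QCParams = QCParams(),
    sample_id: str = "",
) -> QCReport:
    """File-to-file convenience wrapper around :func:`filter_reads`."""
    kept, report = filter_reads(parse_fastq(in_path, sample_id), params)
    write_fastq(kept, out_path)
    return report
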