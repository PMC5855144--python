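"""Locus assignment and per-read repeat-tract measurement.

Replaces the mapper/realigner/repeat-quantifier chain of classic STR
pipelines with a direct, deterministic construction:

1. an optional 3-nt spacer is stripped when it is immediately followed by
   a panel forward primer (the combinatorial-barcoding sub-demultiplexing
   trick);
2. each read is assigned to the locus whose forward (or reverse) primer
   matches the read prefix within a mismatch budget;
3. the repeat-tract length is measured by locating the locus's two 8-base
   flanking anchors in the read and counting the bases between them.

A read contributes to genotyping only if it *spans* the repeat: both
anchors found, and the intervening bases sufficiently motif-pure.  The
allele value is the tract length in bases (ATT x 4 -> allele 12).
Anchor matching is substitution-only; a read with an indel inside a flank
fails to span and is dropped — conservative, mirroring the removal of
reads that fail realignment in mapping-based pipelines.
"""

from __future__ import annotations

import dataclasses
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .panel import FLANK_LEN, LocusDef, Panel, reverse_complement
from .qc import ReadRecord


@dataclasses.dataclass(frozen=True)
class SpanCallParams:
    """Tolerances for primer matching and anchor search.

    ``flank_len`` is the anchor length in bases on each side of the tract;
    ``purity_min`` is the minimum fraction of tract bases matching the
    best circular phase of the motif for a read to count as spanning.
    """

    flank_len: int = FLANK_LEN
    max_anchor_mismatch: int = 1
    max_primer_mismatch: int = 2
    purity_min: float = 0.9
    spacer_set: Optional[tuple[str, ...]] = None

    def __post_init__(self):
        if self.flank_len < 1:
            raise ValueError("flank_len must be >= 1")
        if self.max_anchor_mismatch < 0 or self.max_primer_mismatch < 0:
            raise ValueError("mismatch limits must be >= 0")
        if not 0.0 <= self.purity_min <= 1.0:
            raise ValueError("purity_min must be in [0, 1]")
        if self.spacer_set is not None:
            lens = {len(s) for s in self.spacer_set}
            if len(lens) > 1:
                raise ValueError("all spacers must have the same length")


UNASSIGNED = "unassigned"


@dataclasses.dataclass(frozen=True)
class ReadCall:
    """Outcome of measuring one read against its assigned locus."""

    read_id: str
    locus: str
    orientation: str  # "forward" | "reverse" | "none"
    status: str  # "spanning" | "non_spanning" | "unassigned" | "impure"
    allele_len: Optional[int] = None
    purity: Optional[float] = None


@dataclasses.dataclass
class AlleleTally:
    """Per individual x locus: spanning-read total and counts per allele."""

    individual: str
    locus: str
    counts: dict[int, int]

    @property
    def total_reads(self) -> int:
        return sum(self.counts.values())

    @property
    def n_alleles_detected(self) -> int:
        return len(self.counts)


def _mismatches(a: str, b: str, limit: int) -> int:
    """Hamming distance between equal-length strings, short-circuiting
    once ``limit`` is exceeded (returns limit + 1)."""
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm


def strip_spacer(
    read: ReadRecord, panel: Panel, params: SpanCallParams
) -> tuple[ReadRecord, Optional[str]]:
    """Remove a leading 3-nt spacer when it sits in primer context.

    The spacer is stripped only when the read begins with a configured
    spacer immediately followed by some panel forward primer (within
    ``max_primer_mismatch``); a spacer-looking prefix before non-primer
    sequence is left alone.
    """
    if not params.spacer_set:
        return read, None
    for spacer in params.spacer_set:
        if not read.seq.startswith(spacer):
            continue
        rest = read.seq[len(spacer) :]
        for locus in panel:
            p = locus.primer_f
            if len(rest) >= len(p) and _mismatches(rest[: len(p)], p, params.max_primer_mismatch) <= params.max_primer_mismatch:
                k = len(spacer)
                return (
                    ReadRecord(read.read_id, read.seq[k:], read.quals[k:], read.sample_id),
                    spacer,
                )
    return read, None


def assign_locus(
    read: ReadRecord, panel: Panel, params: SpanCallParams = SpanCallParams()
) -> tuple[str, str]:
    """Assign a read to a locus by primer-prefix matching.

    Forward orientation: the read prefix matches a locus's forward primer.
    Reverse orientation: the prefix matches the reverse primer (the read
    is then the reverse complement of the amplicon).  The fewest-mismatch
    candidate wins; an exact tie between distinct candidates leaves the
    read unassigned.
    """
    best: tuple[int, str, str] | None = None
    tie = False
    for locus in panel:
        for primer, orient in ((locus.primer_f, "forward"), (locus.primer_r, "reverse")):
            if len(read.seq) < len(primer):
                continue
            mm = _mismatches(read.seq[: len(primer)], primer, params.max_primer_mismatch)
            if mm > params.max_primer_mismatch:
                continue
            if best is None or mm < best[0]:
                best = (mm, locus.name, orient)
                tie = False
            elif mm == best[0] and (locus.name, orient) != best[1:]:
                tie = True
    if best is None or tie:
        return UNASSIGNED, "none"
    return best[1], best[2]


def orient_read(read: ReadRecord, orientation: str) -> ReadRecord:
    """Return the read in forward orientation relative to the reference."""
    if orientation == "reverse":
        return ReadRecord(
            read.read_id, reverse_complement(read.seq), read.quals[::-1], read.sample_id
        )
    return read


def _find_anchor(seq: str, anchor: str, start: int, max_mm: int) -> int:
    """Leftmost position >= start where ``anchor`` occurs within ``max_mm``
    substitutions; -1 if absent.  Exact matches are preferred: an exact hit
    anywhere left of the first approximate hit wins by construction of the
    leftmost scan (exact occurrences are also approximate occurrences)."""
    k = len(anchor)
    exact = seq.find(anchor, start)
    limit = exact if exact != -1 else len(seq) - k
    for pos in range(start, limit + 1):
        if _mismatches(seq[pos : pos + k], anchor, max_mm) <= max_mm:
            return pos
    return exact


def tract_purity(tract: str, motif: str) -> float:
    """Fraction of tract bases matching the best circular phase of the
    motif tiled across the tract."""
    if not tract:
        return 0.0
    m = len(motif)
    tiled = motif * (len(tract) // m + 2)
    best = 0
    for phase in range(m):
        ref = tiled[phase : phase + len(tract)]
        best = max(best, sum(a == b for a, b in zip(tract, ref)))
    return best / len(tract)


def measure_allele(
    read: ReadRecord, locus: LocusDef, params: SpanCallParams = SpanCallParams()
) -> ReadCall:
    """Measure the repeat-tract length of a forward-oriented read.

    Locates the 5' anchor (leftmost acceptable occurrence) and the 3'
    anchor (leftmost acceptable occurrence strictly after the 5' anchor
    end); the allele value is the number of bases between them.  Reads
    missing either anchor are ``non_spanning``; reads whose inter-anchor
    bases fall below ``purity_min`` motif purity are ``impure``.
    """
    k = params.flank_len
    a5 = locus.flank5[-k:]
    a3 = locus.flank3[:k]
    p5 = _find_anchor(read.seq, a5, 0, params.max_anchor_mismatch)
    if p5 == -1:
        return ReadCall(read.read_id, locus.name, "forward", "non_spanning")
    tract_start = p5 + k
    p3 = _find_anchor(read.seq, a3, tract_start, params.max_anchor_mismatch)
    if p3 == -1:
        return ReadCall(read.read_id, locus.name, "forward", "non_spanning")
    allele_len = p3 - tract_start
    if allele_len < 1:
        return ReadCall(read.read_id, locus.name, "forward", "non_spanning")
    purity = tract_purity(read.seq[tract_start:p3], locus.motif)
    status = "spanning" if purity >= params.purity_min else "impure"
    return ReadCall(
        read.read_id,
        locus.name,
        "forward",
        status,
        allele_len=allele_len if status == "spanning" else None,
        purity=purity,
    )


def call_read(
    read: ReadRecord, panel: Panel, params: SpanCallParams = SpanCallParams()
) -> ReadCall:
    """Spacer-strip, assign, orient and measure one read."""
    read, _ = strip_spacer(read, panel, params)
    locus_name, orientation = assign_locus(read, panel, params)
    if locus_name == UNASSIGNED:
        return ReadCall(read.read_id, UNASSIGNED, "none", "unassigned")
    call = measure_allele(orient_read(read, orientation), panel[locus_name], params)
    return dataclasses.replace(call, orientation=orientation)


def tally_reads(calls: Iterable[ReadCall], individual: str) -> list[AlleleTally]:
    """Aggregate one individual's spanning calls into per-locus tallies.

    Only ``spanning`` calls are counted; loci with no spanning read yield
    no tally (downstream treats absence as zero depth).
    """
    counters: dict[str, Counter] = defaultdict(Counter)
    for call in calls:
        if call.status == "spanning":
            counters[call.locus][call.allele_len] += 1
    return [
        AlleleTally(individual=individual, locus=locus, counts=dict(sorted(c.items())))
        for locus, c in sorted(counters.items())
    ]


def write_tallies(tallies: Sequence[AlleleTally], path: str | Path) -> None:
    """TSV serialization: individual, locus, total, comma-joined allele:count."""
    with open(path, "w") as fh:
        fh.write("individual\tlocus\ttotal_reads\tallele_counts\n")
        for t in tallies:
            pairs = ",".join(f"{a}:{n}" for a, n in sorted(t.counts.items()))
            fh.write(f"{t.individual}\t{t.locus}\t{t.total_reads}\t{pairs}\n")


def read_tallies(path: str | Path) -> list[AlleleTally]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("individual\t"):
            raise ValueError(f"{path}: not a tally TSV")
        for line in fh:
            ind, locus, _total, pairs = line.rstrip("\n").split("\t")
            counts = {}
            if pairs:
                for item in pairs.split(","):
                    a, n = item.split(":")
                    counts[int(a)] = int(n)
            out.append(AlleleTally(individual=ind, locus=locus, counts=counts))
    return out
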