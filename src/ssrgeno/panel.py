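"""Locus panel: reference amplicons, primers and repeat-tract coordinates.

A *panel* is the set of microsatellite loci an amplicon-sequencing run
targets.  Each locus carries its PCR primers, the repeat motif, a reference
amplicon sequence and the 1-based inclusive coordinates of the repeat tract
within it.  From these, two 8-base flanking anchors are derived — the bases
immediately 5' and 3' of the tract — which the allele caller uses to decide
whether a read spans the whole repeat.

The built-in panel reproduces the published eight-locus *Prochilodus
costatus* design (primers, motifs and amplicon sizes); the flanking
sequence between the primers is synthetic, generated deterministically
from a seed, with the repeat tract fixed at eight motif copies and
centred in the amplicon.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: default seed for :func:`builtin_panel`; fixed so that the shipped panel
#: is identical across installations.
DEFAULT_PANEL_SEED = 20180309

FLANK_LEN = 8

# Published eight-locus P. costatus design: name, forward primer, reverse
# primer, motif, amplicon size (bp).
_BUILTIN_LOCI = [
    ("ProC10", "ATTCCTGTCAATTTCCGGCC", "AGGCCCAAACAGAAGGTAGG", "ATT", 130),
    ("ProC18", "GATCAGACCTCAGACGGGAC", "GTTGTACGGAGATGCACTGC", "CCGT", 197),
    ("ProC22", "AGAGCTGGGATAGGCTCCAGC", "CCTGGACAGGCTCCCAGTCC", "AATG", 130),
    ("ProC36", "GACGGAACGTCTTTAGAACC", "TCTGCACATGCACGAGCGCGG", "AAG", 167),
    ("ProC37", "TGAAGGTGCACAGGGATAGT", "TGTGAAGGTCCTGGAACCCAC", "TTTA", 130),
    ("ProC44", "CTTAGTGAACTGGAGCACG", "GGTCCAGATTGGGCATATACAC", "AAC", 183),
    ("ProC48", "AGCTTAGATGTGTACTAAC", "GTTGAGCAGTGGTGGGGTAC", "AAAG", 153),
    ("ProC49", "GGTGTTTGGTTAATCACCCC", "AGAGATGTGCTTATGCACGC", "AAAG", 146),
]

#: reference tract length, in motif copies, for the built-in panel.  Eight
#: copies satisfies the >=7-repeat marker-selection rule with headroom for
#: one-unit deletion alleles.
REFERENCE_TRACT_COPIES = 8

#: minimum number of tandem motif copies a reference tract must contain.
MIN_REFERENCE_COPIES = 7


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class PanelError(ValueError):
    """Raised when a panel definition violates its invariants."""


@dataclasses.dataclass(frozen=True)
class LocusDef:
    """One microsatellite locus.

    Coordinates are 1-based inclusive, matching the on-disk panel table.
    ``flank5``/``flank3`` are the 8-base anchors immediately before and
    after the repeat tract, derived from ``amplicon_seq``.
    """

    name: str
    primer_f: str
    primer_r: str
    motif: str
    amplicon_seq: str
    repeat_start: int
    repeat_end: int

    @property
    def tract(self) -> str:
        return self.amplicon_seq[self.repeat_start - 1 : self.repeat_end]

    @property
    def tract_len(self) -> int:
        return self.repeat_end - self.repeat_start + 1

    @property
    def flank5(self) -> str:
        return self.amplicon_seq[self.repeat_start - 1 - FLANK_LEN : self.repeat_start - 1]

    @property
    def flank3(self) -> str:
        return self.amplicon_seq[self.repeat_end : self.repeat_end + FLANK_LEN]

    def issues(self) -> list[str]:
        """All invariant violations for this locus (empty when valid)."""
        out: list[str] = []
        n = len(self.amplicon_seq)
        if not (1 <= self.repeat_start <= self.repeat_end <= n):
            out.append(
                f"{self.name}: repeat coordinates [{self.repeat_start}, "
                f"{self.repeat_end}] out of range for {n}-bp amplicon"
            )
            return out
        if self.repeat_start <= FLANK_LEN:
            out.append(
                f"{self.name}: repeat_start {self.repeat_start} leaves less than "
                f"{FLANK_LEN} bases of 5' flank"
            )
        if self.repeat_end > n - FLANK_LEN:
            out.append(
                f"{self.name}: repeat_end {self.repeat_end} leaves less than "
                f"{FLANK_LEN} bases of 3' flank in {n}-bp amplicon"
            )
        if len(self.motif) not in (3, 4):
            out.append(f"{self.name}: motif {self.motif!r} is not tri- or tetra-nucleotide")
        for field in ("primer_f", "primer_r", "motif"):
            seq = getattr(self, field)
            if not seq or set(seq) - set("ACGT"):
                out.append(f"{self.name}: {field} {seq!r} contains non-ACGT characters")
        tract = self.tract
        copies, rem = divmod(len(tract), len(self.motif))
        if rem or tract != self.motif * copies or copies < MIN_REFERENCE_COPIES:
            out.append(
                f"{self.name}: reference tract {tract!r} is not >= "
                f"{MIN_REFERENCE_COPIES} tandem copies of motif {self.motif}"
            )
        if not self.amplicon_seq.startswith(self.primer_f):
            out.append(f"{self.name}: amplicon does not begin with primer_f")
        if not self.amplicon_seq.endswith(reverse_complement(self.primer_r)):
            out.append(f"{self.name}: amplicon does not end with revcomp(primer_r)")
        return out


@dataclasses.dataclass(frozen=True)
class Panel:
    loci: tuple[LocusDef, ...]
    name: str = "panel"

    def __iter__(self):
        return iter(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def __getitem__(self, name: str) -> LocusDef:
        for loc in self.loci:
            if loc.name == name:
                return loc
        raise KeyError(name)


def _occurrences_within(seq: str, pattern: str, max_mm: int) -> list[int]:
    """Start positions where pattern occurs in seq with <= max_mm substitutions."""
    k = len(pattern)
    hits = []
    for pos in range(len(seq) - k + 1):
        window = seq[pos : pos + k]
        mm = sum(a != b for a, b in zip(window, pattern))
        if mm <= max_mm:
            hits.append(pos)
    return hits


def _tandem_similarity(window: str, motif: str) -> int:
    # best match count of an 8-mer against any circular phase of the motif
    best = 0
    m = len(motif)
    tiled = motif * (len(window) // m + 2)
    for phase in range(m):
        ref = tiled[phase : phase + len(window)]
        best = max(best, sum(a == b for a, b in zip(window, ref)))
    return best


def builtin_panel(seed: int = DEFAULT_PANEL_SEED) -> Panel:
    """The eight-locus P. costatus panel with seeded synthetic flanks.

    Primer sequences, motifs and amplicon sizes are the published ones;
    the interior sequence (between the primers, around the tract) is
    pseudo-random from ``seed``.  The tract holds exactly
    :data:`REFERENCE_TRACT_COPIES` motif copies and is centred.  Pure
    function of ``seed``: the same seed always yields byte-identical
    amplicons.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    loci = []
    for name, primer_f, primer_r, motif, size in _BUILTIN_LOCI:
        tract = motif * REFERENCE_TRACT_COPIES
        tail = reverse_complement(primer_r)
        interior = size - len(primer_f) - len(tail) - len(tract)
        if interior < 2 * FLANK_LEN:
            raise PanelError(f"{name}: amplicon size {size} too small for design")
        left_n = interior // 2
        right_n = interior - left_n
        # Rejection-sample the interior so the 8-mers adjacent to the tract
        # do not themselves resemble the motif run (would blur the tract
        # boundary for anchor-based measurement).
        for _ in range(1000):
            left = "".join(rng.choice(bases, size=left_n))
            right = "".join(rng.choice(bases, size=right_n))
            if not (
                _tandem_similarity(left[-FLANK_LEN:], motif) <= 5
                and _tandem_similarity(right[:FLANK_LEN], motif) <= 5
                and left[-1] != motif[0]
                and right[0] != motif[0]
            ):
                continue
            amplicon = primer_f + left + tract + right + tail
            repeat_start = len(primer_f) + left_n + 1
            # Anchors must be unambiguous in the reference even under the
            # caller's 1-mismatch tolerance, or every read at the locus
            # would be systematically mis-measured.
            flank5 = amplicon[repeat_start - 1 - FLANK_LEN : repeat_start - 1]
            flank3 = amplicon[repeat_start - 1 + len(tract) : repeat_start - 1 + len(tract) + FLANK_LEN]
            if (
                _occurrences_within(amplicon, flank5, 1) == [repeat_start - 1 - FLANK_LEN]
                and _occurrences_within(amplicon[repeat_start - 1 :], flank3, 1) == [len(tract)]
            ):
                break
        else:  # pragma: no cover - astronomically unlikely
            raise PanelError(f"{name}: could not generate non-repetitive flanks")
        assert len(amplicon) == size
        loci.append(
            LocusDef(
                name=name,
                primer_f=primer_f,
                primer_r=primer_r,
                motif=motif,
                amplicon_seq=amplicon,
                repeat_start=repeat_start,
                repeat_end=repeat_start + len(tract) - 1,
            )
        )
    return Panel(loci=tuple(loci), name=f"ProC-builtin-seed{seed}")


def load_panel(panel_table_path: str | Path, fasta_path: str | Path, name: str = "panel") -> Panel:
    """Load a panel from a TSV table plus a FASTA of reference amplicons.

    The table needs columns ``name, primer_f, primer_r, motif,
    repeat_start, repeat_end`` (coordinates 1-based inclusive); the FASTA
    records are keyed by locus name.  Every locus is checked against its
    invariants; violations raise :class:`PanelError` naming the locus.
    """
    table = pd.read_csv(panel_table_path, sep="\t", dtype=str)
    required = ["name", "primer_f", "primer_r", "motif", "repeat_start", "repeat_end"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise PanelError(f"panel table missing columns: {', '.join(missing)}")
    refs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    loci = []
    for row in table.itertuples(index=False):
        if row.name not in refs:
            raise PanelError(f"{row.name}: no FASTA record for this locus")
        locus = LocusDef(
            name=row.name,
            primer_f=row.primer_f.upper(),
            primer_r=row.primer_r.upper(),
            motif=row.motif.upper(),
            amplicon_seq=refs[row.name],
            repeat_start=int(row.repeat_start),
            repeat_end=int(row.repeat_end),
        )
        problems = locus.issues()
        if problems:
            raise PanelError("; ".join(problems))
        loci.append(locus)
    panel = Panel(loci=tuple(loci), name=name)
    cross = _cross_locus_issues(panel)
    if cross:
        raise PanelError("; ".join(cross))
    return panel


def write_panel(panel: Panel, panel_table_path: str | Path, fasta_path: str | Path) -> None:
    """Serialize a panel to the TSV + FASTA pair read by :func:`load_panel`."""
    rows = [
        {
            "name": loc.name,
            "primer_f": loc.primer_f,
            "primer_r": loc.primer_r,
            "motif": loc.motif,
            "repeat_start": loc.repeat_start,
            "repeat_end": loc.repeat_end,
        }
        for loc in panel
    ]
    pd.DataFrame(rows, columns=["name", "primer_f", "primer_r", "motif", "repeat_start", "repeat_end"]).to_csv(
        panel_table_path, sep="\t", index=False
    )
    with open(fasta_path, "w") as fh:
        for loc in panel:
            fh.write(f">{loc.name}\n{loc.amplicon_seq}\n")


def _cross_locus_issues(panel: Panel) -> list[str]:
    out: list[str] = []
    seen_names: set[str] = set()
    seen_pf: dict[str, str] = {}
    seen_pairs: dict[tuple[str, str], str] = {}
    for loc in panel:
        if loc.name in seen_names:
            out.append(f"duplicate locus name: {loc.name}")
        seen_names.add(loc.name)
        if loc.primer_f in seen_pf and seen_pf[loc.primer_f] != loc.name:
            out.append(f"loci {seen_pf[loc.primer_f]} and {loc.name} share forward primer")
        seen_pf.setdefault(loc.primer_f, loc.name)
        pair = (loc.primer_f, loc.primer_r)
        if pair in seen_pairs and seen_pairs[pair] != loc.name:
            out.append(f"loci {seen_pairs[pair]} and {loc.name} share the primer pair")
        seen_pairs.setdefault(pair, loc.name)
    return out


def validate_panel(panel: Panel) -> list[str]:
    """All invariant violations across the panel; empty list means valid.

    Issues are returned, never raised, so callers can report them all.
    """
    issues: list[str] = []
    for loc in panel:
        issues.extend(loc.issues())
    issues.extend(_cross_locus_issues(panel))
    return issues
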