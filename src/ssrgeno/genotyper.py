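"""Genotype filtering: tallies -> hom/het/NA calls, matrix and exports.

A per-individual, per-locus tally of spanning reads becomes a genotype
under three filter criteria:

1. at most two alleles per individual per locus;
2. at least ``min_reads`` spanning reads at the locus (default 10);
3. a second allele is accepted only when it carries at least
   ``het_min_fraction`` of the locus's spanning reads (default 20 %);
   below that the individual is called homozygous for the top allele.

Cells failing any criterion are NA.  Both thresholds are inclusive ("at
least").  The 20 % denominator is the locus's total spanning reads.
Minor alleles below the 20 % threshold (typically stutter) are ignored
entirely; more than two alleles *above* it makes the cell NA.  Ranking
ties break toward the shorter allele so calls are deterministic.

The ``na_reason`` field records why a cell is NA (low depth, excess
alleles, no data, ...); it is diagnostic only and never changes which
cells are NA.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .panel import Panel
from .repeat_caller import AlleleTally

DEFAULT_MIN_READS = 10
DEFAULT_HET_MIN_FRACTION = 0.20


@dataclasses.dataclass(frozen=True)
class FilterCriteria:
    min_reads: int = DEFAULT_MIN_READS
    het_min_fraction: float = DEFAULT_HET_MIN_FRACTION
    max_alleles: int = 2

    def __post_init__(self):
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 < self.het_min_fraction <= 0.5:
            raise ValueError("het_min_fraction must be in (0, 0.5]")
        if self.max_alleles != 2:
            raise ValueError("max_alleles is fixed at 2 for diploid calling")


@dataclasses.dataclass(frozen=True)
class GenotypeCall:
    individual: str
    locus: str
    status: str  # "hom" | "het" | "NA"
    alleles: Optional[tuple[int, int]] = None  # ascending; equal for hom
    total_reads: int = 0
    support: Optional[tuple[int, ...]] = None  # read counts of called alleles
    na_reason: Optional[str] = None

    @property
    def is_called(self) -> bool:
        return self.status != "NA"


def call_genotype(
    tally: Optional[AlleleTally],
    criteria: FilterCriteria = FilterCriteria(),
    individual: str = "",
    locus: str = "",
) -> GenotypeCall:
    """Apply the filter criteria to one tally.

    Decision procedure: (a) no tally or depth below ``min_reads`` -> NA;
    (b) rank alleles by count, descending, count ties broken toward the
    shorter allele; qualifying set S = alleles with count/total >=
    ``het_min_fraction``; (c) more than two qualifying -> NA; (d) top
    allele not qualifying -> NA; then het if two qualify, hom if one.
    """
    if tally is not None:
        individual = individual or tally.individual
        locus = locus or tally.locus
    if tally is None or tally.total_reads == 0:
        return GenotypeCall(individual, locus, "NA", na_reason="no_data")
    total = tally.total_reads
    if total < criteria.min_reads:
        return GenotypeCall(individual, locus, "NA", total_reads=total, na_reason="low_depth")
    ranked = sorted(tally.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    qualifying = [(a, c) for a, c in ranked if c / total >= criteria.het_min_fraction]
    if len(qualifying) > criteria.max_alleles:
        return GenotypeCall(individual, locus, "NA", total_reads=total, na_reason="excess_alleles")
    if not qualifying or ranked[0][0] != qualifying[0][0]:
        return GenotypeCall(individual, locus, "NA", total_reads=total, na_reason="no_majority")
    if len(qualifying) == 2:
        # guard: a rank-3 allele tied with rank 2 and also qualifying would
        # make the pair ambiguous; unreachable when <=2 qualify, kept for
        # clarity of the contract.
        if len(ranked) > 2 and ranked[2][1] == qualifying[1][1] and ranked[2][1] / total >= criteria.het_min_fraction:
            return GenotypeCall(  # pragma: no cover
                individual, locus, "NA", total_reads=total, na_reason="ambiguous_tie"
            )
        (a1, c1), (a2, c2) = qualifying
        lo, hi = sorted((a1, a2))
        support = (c1, c2) if (a1, a2) == (lo, hi) else (c2, c1)
        return GenotypeCall(individual, locus, "het", alleles=(lo, hi), total_reads=total, support=support)
    a, c = qualifying[0]
    return GenotypeCall(individual, locus, "hom", alleles=(a, a), total_reads=total, support=(c,))


@dataclasses.dataclass
class GenotypeMatrix:
    """Complete individuals x loci grid of genotype calls."""

    calls: dict[tuple[str, str], GenotypeCall]
    individuals: list[str]
    loci: list[str]

    def __getitem__(self, key: tuple[str, str]) -> GenotypeCall:
        return self.calls[key]

    @property
    def n_cells(self) -> int:
        return len(self.individuals) * len(self.loci)

    @property
    def n_na(self) -> int:
        return sum(1 for c in self.calls.values() if not c.is_called)

    @property
    def na_fraction(self) -> float:
        return self.n_na / self.n_cells if self.n_cells else 0.0


def genotype_cohort(
    tallies: Iterable[AlleleTally],
    panel: Panel,
    individuals: Sequence[str],
    criteria: FilterCriteria = FilterCriteria(),
) -> GenotypeMatrix:
    """Call every individual x locus cell; absent tallies become NA/no_data.

    Tallies naming an unknown individual or locus are reported (returned
    matrix is unaffected) and skipped.
    """
    loci = panel.locus_names
    known = set(individuals)
    by_cell: dict[tuple[str, str], AlleleTally] = {}
    skipped: list[str] = []
    for t in tallies:
        if t.individual not in known or t.locus not in loci:
            skipped.append(f"{t.individual}/{t.locus}")
            continue
        by_cell[(t.individual, t.locus)] = t
    calls = {
        (ind, locus): call_genotype(by_cell.get((ind, locus)), criteria, ind, locus)
        for ind in individuals
        for locus in loci
    }
    matrix = GenotypeMatrix(calls=calls, individuals=list(individuals), loci=list(loci))
    matrix.skipped_tallies = skipped  # type: ignore[attr-defined]
    return matrix


def _cell_text(call: GenotypeCall) -> str:
    if not call.is_called:
        return "NA"
    a1, a2 = call.alleles
    return f"{a1}/{a2}"


def write_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    """CSV: one row per individual, one column per locus, cells "a1/a2" or NA."""
    rows = {
        ind: {locus: _cell_text(matrix[(ind, locus)]) for locus in matrix.loci}
        for ind in matrix.individuals
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=matrix.loci)
    df.index.name = "individual"
    df.to_csv(path)


def read_matrix(path: str | Path, panel: Panel) -> GenotypeMatrix:
    """Companion reader for :func:`write_matrix` (statuses reconstructed
    from cell text; depths and NA reasons are not round-tripped)."""
    df = pd.read_csv(path, index_col="individual", dtype=str)
    calls: dict[tuple[str, str], GenotypeCall] = {}
    for ind in df.index:
        for locus in df.columns:
            text = df.loc[ind, locus]
            if text == "NA" or pd.isna(text):
                calls[(ind, locus)] = GenotypeCall(ind, locus, "NA", na_reason="no_data")
            else:
                a1, a2 = (int(x) for x in text.split("/"))
                status = "hom" if a1 == a2 else "het"
                calls[(ind, locus)] = GenotypeCall(ind, locus, status, alleles=(a1, a2))
    return GenotypeMatrix(calls=calls, individuals=list(df.index), loci=list(df.columns))


def write_genepop(matrix: GenotypeMatrix, path: str | Path, title: str = "ssrgeno export") -> None:
    """GenePop dialect: title, one locus name per line, "Pop", then one
    line per individual with two zero-padded 3-digit alleles per locus
    (missing = 000000)."""
    for call in matrix.calls.values():
        if call.alleles and max(call.alleles) > 999:
            raise ValueError(
                f"{call.individual}/{call.locus}: allele {max(call.alleles)} "
                "exceeds GenePop's 3-digit limit"
            )
    lines = [title]
    lines.extend(matrix.loci)
    lines.append("Pop")
    for ind in matrix.individuals:
        codes = []
        for locus in matrix.loci:
            call = matrix[(ind, locus)]
            if call.is_called:
                a1, a2 = call.alleles
                codes.append(f"{a1:03d}{a2:03d}")
            else:
                codes.append("000000")
        lines.append(f"{ind} , " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")
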