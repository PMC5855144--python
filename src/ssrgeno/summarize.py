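"""Run-level metrics: efficiency, read distribution, allele richness,
depth, reads-vs-samples regression, and multiplexing capacity.

*Amplification efficiency* of a locus is the percentage of individuals
successfully genotyped (non-NA) at that locus.  *Read distribution* is
each locus's share of the run's spanning reads.  Mean depth is taken
over the full individuals x loci grid, counting empty cells as zero.
Percentages are reported to two decimals, rounded half-up, matching the
conventional table style.

Capacity planning inverts the depth arithmetic: given a read budget R,
N individuals, L loci and a minimum usable depth m (default 10 reads),
the expected depth at a locus with read share w is R*w/N; a run is
feasible when the worst locus still clears m, and under uniform shares
the maximum locus count is floor(R/(N*m)) (equivalently, the maximum
cohort is floor(R/(L*m)) individuals).
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

from scipy import stats

from .genotyper import GenotypeMatrix
from .repeat_caller import AlleleTally

DEFAULT_MIN_DEPTH = 10


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (spreadsheet convention), e.g. 0.125 -> 0.13."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def locus_efficiency(matrix: GenotypeMatrix) -> dict[str, float]:
    """Per-locus percentage of individuals with a non-NA call (2 d.p.)."""
    if not matrix.individuals or not matrix.loci:
        raise ValueError("empty genotype matrix")
    n = len(matrix.individuals)
    out = {}
    for locus in matrix.loci:
        called = sum(1 for ind in matrix.individuals if matrix[(ind, locus)].is_called)
        out[locus] = round_half_up(100.0 * called / n)
    return out


def read_distribution(tallies: Iterable[AlleleTally]) -> dict[str, float]:
    """Per-locus spanning-read shares, as percentages summing to ~100."""
    totals: dict[str, int] = defaultdict(int)
    for t in tallies:
        totals[t.locus] += t.total_reads
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("no spanning reads")
    return {locus: round_half_up(100.0 * n / grand) for locus, n in sorted(totals.items())}


def allele_summary(matrix: GenotypeMatrix) -> tuple[dict[str, int], int]:
    """Distinct alleles per locus over called cells only, plus the total."""
    per_locus = {}
    for locus in matrix.loci:
        seen: set[int] = set()
        for ind in matrix.individuals:
            call = matrix[(ind, locus)]
            if call.is_called:
                seen.update(call.alleles)
        per_locus[locus] = len(seen)
    return per_locus, sum(per_locus.values())


def depth_stats(
    tallies: Iterable[AlleleTally], n_individuals: int, n_loci: int
) -> tuple[float, dict[str, float]]:
    """Mean spanning reads per cell over the full grid (missing cells are
    zero), plus per-locus means over individuals."""
    if n_individuals <= 0 or n_loci <= 0:
        raise ValueError("n_individuals and n_loci must be positive")
    per_locus: dict[str, int] = defaultdict(int)
    grand = 0
    for t in tallies:
        per_locus[t.locus] += t.total_reads
        grand += t.total_reads
    mean_cell = grand / (n_individuals * n_loci)
    locus_means = {locus: n / n_individuals for locus, n in sorted(per_locus.items())}
    return mean_cell, locus_means


def reads_vs_samples_fit(points: Sequence[tuple[float, float]]) -> tuple[float, float, float]:
    """OLS fit of mean reads-per-individual against cohort size.

    Returns (slope, intercept, Pearson correlation).  Cohort size must
    take at least two distinct values.
    """
    if len(points) < 2 or len({x for x, _ in points}) < 2:
        raise ValueError("need >= 2 points with distinct x values")
    xs = [float(x) for x, _ in points]
    ys = [float(y) for _, y in points]
    if len(set(ys)) == 1:
        return 0.0, ys[0], 0.0  # degenerate: constant response
    fit = stats.linregress(xs, ys)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


@dataclasses.dataclass
class RunSummary:
    efficiency_pct: dict[str, float]
    read_share_pct: dict[str, float]
    n_distinct_alleles: dict[str, int]
    mean_reads_per_individual: dict[str, float]
    total_alleles: int
    mean_reads_per_cell: float
    na_fraction: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def write_tsv(self, path: str | Path) -> None:
        """Human-readable per-locus table (efficiency / share / alleles / depth)."""
        loci = list(self.efficiency_pct)
        with open(path, "w") as fh:
            fh.write("locus\tefficiency_pct\tread_share_pct\tn_alleles\tmean_reads_per_individual\n")
            for locus in loci:
                fh.write(
                    f"{locus}\t{self.efficiency_pct.get(locus, 0.0):.2f}"
                    f"\t{self.read_share_pct.get(locus, 0.0):.2f}"
                    f"\t{self.n_distinct_alleles.get(locus, 0)}"
                    f"\t{self.mean_reads_per_individual.get(locus, 0.0):.2f}\n"
                )
            fh.write(
                f"TOTAL\t\t\t{self.total_alleles}\t{self.mean_reads_per_cell:.2f}\n"
            )


def summarize_run(matrix: GenotypeMatrix, tallies: Sequence[AlleleTally]) -> RunSummary:
    per_locus_alleles, total = allele_summary(matrix)
    mean_cell, locus_means = depth_stats(tallies, len(matrix.individuals), len(matrix.loci))
    try:
        shares = read_distribution(tallies)
    except ValueError:
        shares = {locus: 0.0 for locus in matrix.loci}
    return RunSummary(
        efficiency_pct=locus_efficiency(matrix),
        read_share_pct=shares,
        n_distinct_alleles=per_locus_alleles,
        mean_reads_per_individual={locus: locus_means.get(locus, 0.0) for locus in matrix.loci},
        total_alleles=total,
        mean_reads_per_cell=mean_cell,
        na_fraction=matrix.na_fraction,
    )


@dataclasses.dataclass
class CapacityEstimate:
    reads_budget: int
    n_individuals: int
    n_loci: int
    min_depth: int
    locus_weights: Optional[dict[str, float]]
    expected_depth: dict[str, float]
    feasible: bool
    limiting_locus: Optional[str]
    scale_factor: float
    max_uniform_loci: int
    max_individuals: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def capacity_estimate(
    reads_budget: int,
    n_individuals: int,
    n_loci: int,
    min_depth: int = DEFAULT_MIN_DEPTH,
    locus_weights: Optional[dict[str, float]] = None,
) -> CapacityEstimate:
    """How far a read budget stretches at a minimum per-cell depth.

    With empirical weights the limiting locus is the lowest-share one and
    ``scale_factor`` = min over loci of expected depth / min_depth (how
    many times the design could be scaled up, <1 meaning infeasible).
    Uniform-weight bounds are always reported alongside: the optimistic
    ceiling ``floor(R/(N*m))`` loci or ``floor(R/(L*m))`` individuals.
    """
    if reads_budget <= 0 or n_individuals <= 0 or n_loci <= 0 or min_depth <= 0:
        raise ValueError("all capacity inputs must be positive")
    if locus_weights:
        total_w = sum(locus_weights.values())
        weights = {k: v / total_w for k, v in locus_weights.items()}
    else:
        weights = {f"locus{i + 1}": 1.0 / n_loci for i in range(n_loci)}
    expected = {k: reads_budget * w / n_individuals for k, w in weights.items()}
    limiting = min(expected, key=lambda k: (expected[k], k))
    scale = expected[limiting] / min_depth
    return CapacityEstimate(
        reads_budget=reads_budget,
        n_individuals=n_individuals,
        n_loci=n_loci,
        min_depth=min_depth,
        locus_weights=weights if locus_weights else None,
        expected_depth={k: round(v, 2) for k, v in expected.items()},
        feasible=all(v >= min_depth for v in expected.values()),
        limiting_locus=limiting,
        scale_factor=scale,
        max_uniform_loci=reads_budget // (n_individuals * min_depth),
        max_individuals=reads_budget // (n_loci * min_depth),
    )
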