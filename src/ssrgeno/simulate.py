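"""Amplicon-read simulator with known genotypes, stutter and base errors.

The study's raw sequencing runs are not deposited, so the simulator is
the package's stand-in for a MiSeq amplicon run: it draws a diploid
genotype per individual per locus from configurable allele pools, then
emits per-sample FASTQ files in which each read is the full reference
amplicon with the repeat tract resized to the sampled allele, optionally
perturbed by

* PCR stutter — a per-read Bernoulli event shifting the tract by exactly
  one motif unit, shortening with probability ``1 - p_expand`` (slippage
  predominantly contracts tri-/tetra-nucleotide repeats);
* per-base substitution errors at rate ``sub_error``;
* per-position Phred qualities drawn around a profile with a declining
  3' tail.

Read yields are uneven by design: the default per-locus read shares are
the highly skewed empirical shares of the paper's 384-individual run
(run 6), and per-individual depth is modulated by a lognormal yield
factor.  A fixed-depth mode (``reads_per_cell``) bypasses the yield
model and emits an exact read count per individual x locus cell, which
is what parameter-recovery tests want.

All randomness flows from a single seeded generator; the same config and
seed reproduce byte-identical FASTQ output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .panel import LocusDef, Panel
from .qc import ReadRecord, write_fastq

#: per-locus read shares of the paper's run 6 (ProC10..ProC49, percent;
#: they sum to exactly 100) — reproduces the extreme unevenness of a real
#: pseudo-multiplex pool.
RUN6_LOCUS_SHARES = {
    "ProC10": 5.44,
    "ProC18": 3.01,
    "ProC22": 14.52,
    "ProC36": 19.02,
    "ProC37": 0.21,
    "ProC44": 2.49,
    "ProC48": 3.81,
    "ProC49": 51.50,
}

#: per-locus distinct-allele counts of the run-6 cohort (total 53, with
#: ProC49 richest at 10 and ProC10 poorest at 4); only the total and the
#: two extremes are published, the interior split is this package's
#: fixture choice.
RUN6_POOL_SIZES = {
    "ProC10": 4,
    "ProC18": 6,
    "ProC22": 6,
    "ProC36": 7,
    "ProC37": 6,
    "ProC44": 7,
    "ProC48": 7,
    "ProC49": 10,
}


def default_qual_profile(read_length: int = 230) -> tuple[int, ...]:
    """Mean Phred per position: Q37 plateau, declining toward the 3' end."""
    pos = np.arange(read_length)
    mean = np.where(pos < 150, 37.0, 37.0 - (pos - 150) * (7.0 / 80.0))
    return tuple(int(round(q)) for q in mean)


def run6_allele_pool(locus: LocusDef, n_alleles: int) -> dict[int, float]:
    """A uniform-frequency allele pool of ``n_alleles`` distinct tract
    lengths centred on the reference (8 motif copies), in whole motif
    units."""
    m = len(locus.motif)
    ref_copies = locus.tract_len // m
    lo = ref_copies - n_alleles // 2
    if lo < 2:
        lo = 2
    lengths = [(lo + i) * m for i in range(n_alleles)]
    return {length: 1.0 / n_alleles for length in lengths}


@dataclasses.dataclass
class SimulationConfig:
    """Study-condition knobs for one simulated run.

    Defaults emulate the paper's run 6: 384 individuals, ~1 M-read Nano
    cartridge yielding ~991 k usable reads, run-6 locus shares and
    allele-pool sizes.
    """

    n_individuals: int = 384
    total_reads: int = 991_337
    locus_weights: Optional[dict[str, float]] = None  # None -> run-6 shares
    allele_pool: Optional[dict[str, dict[int, float]]] = None  # None -> run-6 pools
    het_rate: Optional[float] = None  # None -> Hardy-Weinberg-style free draw
    p_stutter: float = 0.02
    p_expand: float = 0.25
    sub_error: float = 0.001
    qual_profile: Optional[Sequence[int]] = None
    qual_sd: float = 3.0
    read_length: int = 230
    spacer_set: Optional[tuple[str, ...]] = None
    individual_yield_cv: float = 0.3
    reads_per_cell: Optional[int] = None  # fixed-depth mode
    force_allele_coverage: bool = False  # every pool allele in >=2 individuals
    gzip_output: bool = False
    seed: int = 0

    def resolved_weights(self, panel: Panel) -> dict[str, float]:
        if self.locus_weights is None:
            if set(panel.locus_names) == set(RUN6_LOCUS_SHARES):
                raw = {k: RUN6_LOCUS_SHARES[k] for k in panel.locus_names}
            else:
                raw = {name: 1.0 for name in panel.locus_names}
        else:
            raw = dict(self.locus_weights)
        missing = set(panel.locus_names) - set(raw)
        if missing:
            raise ValueError(f"locus_weights missing loci: {sorted(missing)}")
        total = sum(raw.values())
        if total <= 0:
            raise ValueError("locus_weights must have positive sum")
        return {k: v / total for k, v in raw.items()}

    def resolved_pools(self, panel: Panel) -> dict[str, dict[int, float]]:
        if self.allele_pool is not None:
            pools = self.allele_pool
        else:
            pools = {
                loc.name: run6_allele_pool(loc, RUN6_POOL_SIZES.get(loc.name, 6))
                for loc in panel
            }
        for loc in panel:
            pool = pools.get(loc.name)
            if not pool:
                raise ValueError(f"empty allele pool for locus {loc.name}")
            m = len(loc.motif)
            for length in pool:
                if length <= 0 or length % m:
                    raise ValueError(
                        f"{loc.name}: pool allele {length} is not a positive "
                        f"multiple of motif length {m}"
                    )
        return pools

    def validate(self, panel: Panel) -> None:
        for p, label in [
            (self.p_stutter, "p_stutter"),
            (self.p_expand, "p_expand"),
            (self.sub_error, "sub_error"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1]")
        if self.het_rate is not None and not 0.0 <= self.het_rate <= 1.0:
            raise ValueError("het_rate must be in [0, 1]")
        w = self.resolved_weights(panel)
        assert abs(sum(w.values()) - 1.0) < 1e-9
        self.resolved_pools(panel)


@dataclasses.dataclass
class TruthTable:
    """Known diploid genotypes: (individual, locus) -> (a1, a2), a1 <= a2."""

    genotypes: dict[tuple[str, str], tuple[int, int]]
    individuals: list[str]
    loci: list[str]

    def __getitem__(self, key: tuple[str, str]) -> tuple[int, int]:
        return self.genotypes[key]

    def n_cells(self) -> int:
        return len(self.genotypes)


def individual_ids(n: int) -> list[str]:
    return [f"ind{idx:04d}" for idx in range(1, n + 1)]


def sample_genotypes(panel: Panel, config: SimulationConfig) -> TruthTable:
    """Draw a diploid genotype per individual per locus from the pools.

    Two alleles are drawn independently from the pool frequencies; with
    ``het_rate`` set, heterozygosity is instead forced per cell by
    rejection.  With ``force_allele_coverage``, haplotypes are reassigned
    (deterministically, from the seed) until every pool allele is carried
    by at least two individuals — used for allele-richness recovery runs.
    """
    config.validate(panel)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    pools = config.resolved_pools(panel)
    inds = individual_ids(config.n_individuals)
    genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    for locus in panel:
        pool = pools[locus.name]
        alleles = np.array(sorted(pool))
        freqs = np.array([pool[a] for a in sorted(pool)], dtype=float)
        freqs = freqs / freqs.sum()
        n = config.n_individuals
        if config.het_rate is None:
            hap = rng.choice(alleles, size=(n, 2), p=freqs)
        else:
            hap = np.empty((n, 2), dtype=int)
            het = rng.random(n) < config.het_rate
            for i in range(n):
                a = rng.choice(alleles, p=freqs)
                if het[i] and len(alleles) > 1:
                    b = a
                    while b == a:
                        b = rng.choice(alleles, p=freqs)
                else:
                    b = a
                hap[i] = (a, b)
        if config.force_allele_coverage:
            hap = _force_coverage(hap, alleles, rng)
        for i, ind in enumerate(inds):
            a1, a2 = int(hap[i, 0]), int(hap[i, 1])
            genotypes[(ind, locus.name)] = (min(a1, a2), max(a1, a2))
    return TruthTable(genotypes=genotypes, individuals=inds, loci=panel.locus_names)


def _force_coverage(hap: np.ndarray, alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Reassign haplotypes until every allele has >= 2 carrier individuals,
    never dropping another allele below 2 carriers."""
    hap = hap.copy()
    n = hap.shape[0]
    if n < 2 * len(alleles):
        raise ValueError("too few individuals to cover every pool allele twice")

    def carriers(a: int) -> set[int]:
        return {i for i in range(n) if a in hap[i]}

    for allele in alleles:
        while len(carriers(int(allele))) < 2:
            # steal a haplotype from an individual whose alleles are all abundant
            order = rng.permutation(n)
            for i in order:
                if int(allele) in hap[i]:
                    continue
                j = int(rng.integers(2))
                donor = int(hap[i, j])
                if len(carriers(donor)) > 2 or donor == int(allele):
                    hap[i, j] = allele
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not force allele coverage")
    return hap


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _apply_substitutions(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _read_sequence(locus: LocusDef, allele_len: int) -> str:
    """Reference amplicon with the tract resized to ``allele_len`` bases."""
    m = len(locus.motif)
    copies = allele_len // m
    tract = (locus.motif * (copies + 1))[:allele_len]
    return (
        locus.amplicon_seq[: locus.repeat_start - 1]
        + tract
        + locus.amplicon_seq[locus.repeat_end :]
    )


@dataclasses.dataclass
class SimulatedSample:
    sample_id: str
    fastq: str
    n_reads: int
    spacer: Optional[str] = None


@dataclasses.dataclass
class Manifest:
    samples: list[SimulatedSample]
    seed: int
    truth_path: Optional[str] = None

    @property
    def total_reads(self) -> int:
        return sum(s.n_reads for s in self.samples)

    def write_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "total_reads": self.total_reads,
            "truth": self.truth_path,
            "samples": [dataclasses.asdict(s) for s in self.samples],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def simulate_reads(
    panel: Panel, truth: TruthTable, config: SimulationConfig, out_dir: str | Path
) -> Manifest:
    """Emit one FASTQ per individual (per individual x spacer when a
    spacer set is configured) and return the manifest.

    Expected reads per (individual, locus) cell is
    ``total_reads x locus_weight / n_individuals`` scaled by a lognormal
    per-individual yield factor, realized as a Poisson draw — unless
    ``reads_per_cell`` fixes the depth exactly.
    """
    config.validate(panel)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    weights = config.resolved_weights(panel)
    profile = tuple(config.qual_profile) if config.qual_profile else default_qual_profile(config.read_length)

    if config.individual_yield_cv > 0:
        cv = config.individual_yield_cv
        sigma = float(np.sqrt(np.log(1.0 + cv * cv)))
        yields = rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(truth.individuals))
    else:
        yields = np.ones(len(truth.individuals))

    samples: list[SimulatedSample] = []
    ext = ".fastq.gz" if config.gzip_output else ".fastq"
    for i, ind in enumerate(truth.individuals):
        spacer = None
        if config.spacer_set:
            spacer = config.spacer_set[i % len(config.spacer_set)]
        reads: list[ReadRecord] = []
        serial = 0
        for locus in panel:
            a1, a2 = truth[(ind, locus.name)]
            if config.reads_per_cell is not None:
                n_reads = config.reads_per_cell
            else:
                lam = config.total_reads * weights[locus.name] / config.n_individuals
                n_reads = int(rng.poisson(lam * yields[i]))
            # Both haplotypes amplify equally: reads split as evenly as the
            # count allows (odd remainder assigned at random), so a
            # heterozygote's minor allele holds ~50% of clean reads and the
            # 20% rule recovers it whenever depth is adequate.
            half = n_reads // 2
            hap_alleles = [a1] * half + [a2] * (n_reads - half)
            if n_reads % 2 and rng.random() < 0.5:
                hap_alleles[half] = a1
                hap_alleles[-1] = a2
            rng.shuffle(hap_alleles)
            for allele in hap_alleles:
                if rng.random() < config.p_stutter:
                    shift = len(locus.motif) if rng.random() < config.p_expand else -len(locus.motif)
                    # a contraction below one motif copy is resampled as no-op
                    if allele + shift >= len(locus.motif):
                        allele = allele + shift
                seq = _read_sequence(locus, allele)
                if spacer:
                    seq = spacer + seq
                seq = seq[: config.read_length]
                seq = _apply_substitutions(seq, rng, config.sub_error)
                mean_q = np.asarray(profile[: len(seq)], dtype=float)
                if len(mean_q) < len(seq):  # pragma: no cover - profile shorter than read
                    mean_q = np.pad(mean_q, (0, len(seq) - len(mean_q)), constant_values=mean_q[-1])
                quals = np.clip(
                    np.rint(rng.normal(mean_q, config.qual_sd)), 2, 41
                ).astype(int)
                serial += 1
                reads.append(
                    ReadRecord(
                        read_id=f"sim:{ind}:{serial}",
                        seq=seq,
                        quals=tuple(int(q) for q in quals),
                        sample_id=ind,
                    )
                )
        fname = f"{ind}_{spacer}{ext}" if spacer else f"{ind}{ext}"
        fpath = out_dir / fname
        n_written = write_fastq(reads, fpath)
        samples.append(SimulatedSample(sample_id=ind, fastq=str(fpath), n_reads=n_written, spacer=spacer))
    return Manifest(samples=samples, seed=config.seed)


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """TSV schema: individual, locus, allele1, allele2 (allele1 <= allele2)."""
    with open(path, "w") as fh:
        fh.write("individual\tlocus\tallele1\tallele2\n")
        for ind in truth.individuals:
            for locus in truth.loci:
                a1, a2 = truth[(ind, locus)]
                fh.write(f"{ind}\t{locus}\t{a1}\t{a2}\n")


def read_truth(path: str | Path) -> TruthTable:
    genotypes: dict[tuple[str, str], tuple[int, int]] = {}
    individuals: list[str] = []
    loci: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["individual", "locus", "allele1", "allele2"]:
            raise ValueError(f"{path}: not a truth TSV")
        for line in fh:
            ind, locus, a1, a2 = line.rstrip("\n").split("\t")
            genotypes[(ind, locus)] = (int(a1), int(a2))
            if ind not in individuals:
                individuals.append(ind)
            if locus not in loci:
                loci.append(locus)
    return TruthTable(genotypes=genotypes, individuals=individuals, loci=loci)


def write_samplesheet(manifest: Manifest, path: str | Path) -> None:
    """Samplesheet CSV consumed by the pipeline: sample_id, fastq, spacer."""
    with open(path, "w") as fh:
        fh.write("sample_id,fastq,spacer\n")
        for s in manifest.samples:
            fh.write(f"{s.sample_id},{s.fastq},{s.spacer or ''}\n")
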