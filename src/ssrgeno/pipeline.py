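"""End-to-end orchestration: FASTQ in, genotype matrix and summaries out.

``run_pipeline`` chains the stages in their fixed order — quality filter,
spacer stripping, locus assignment, repeat-tract measurement, tallying,
genotype filtering, summarization — and writes every output plus a
provenance record (config hash, parameter values, package version) so a
rerun with identical inputs reproduces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .genotyper import FilterCriteria, GenotypeMatrix, genotype_cohort, write_genepop, write_matrix
from .panel import Panel, builtin_panel, load_panel, validate_panel
from .qc import QCParams, QCReport, filter_reads, parse_fastq
from .repeat_caller import AlleleTally, SpanCallParams, call_read, tally_reads, write_tallies
from .summarize import RunSummary, summarize_run

logger = logging.getLogger("ssrgeno")


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2 at the CLI)."""


class InputError(ValueError):
    """Missing or empty inputs (exit code 3 at the CLI)."""


@dataclasses.dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults are the pipeline's
    published thresholds (Q30, 75 bp, 8-base flanks, 10 reads, 20 %,
    two alleles)."""

    samplesheet: str
    out_dir: str
    panel_table: Optional[str] = None
    panel_fasta: Optional[str] = None
    builtin_panel_seed: Optional[int] = None  # used when no panel files given
    qc: QCParams = dataclasses.field(default_factory=QCParams)
    span: SpanCallParams = dataclasses.field(default_factory=SpanCallParams)
    criteria: FilterCriteria = dataclasses.field(default_factory=FilterCriteria)
    genepop_title: str = "ssrgeno run"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            qc = QCParams(**raw.pop("qc", {}))
            span_kwargs = raw.pop("span", {})
            if isinstance(span_kwargs.get("spacer_set"), list):
                span_kwargs["spacer_set"] = tuple(span_kwargs["spacer_set"])
            span = SpanCallParams(**span_kwargs)
            criteria = FilterCriteria(**raw.pop("criteria", {}))
            return cls(qc=qc, span=span, criteria=criteria, **raw)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config_panel(config: RunConfig) -> Panel:
    if config.panel_table and config.panel_fasta:
        panel = load_panel(config.panel_table, config.panel_fasta)
    elif config.panel_table or config.panel_fasta:
        raise ConfigError("panel_table and panel_fasta must be given together")
    else:
        panel = builtin_panel() if config.builtin_panel_seed is None else builtin_panel(config.builtin_panel_seed)
    issues = validate_panel(panel)
    if issues:
        raise ConfigError("invalid panel: " + "; ".join(issues))
    return panel


def read_samplesheet(path: str | Path) -> list[tuple[str, str, Optional[str]]]:
    """CSV with header sample_id, fastq, spacer (spacer optional/blank)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"samplesheet not found: {path}")
    rows: list[tuple[str, str, Optional[str]]] = []
    with open(path) as fh:
        header = [c.strip() for c in fh.readline().rstrip("\n").split(",")]
        if header[:2] != ["sample_id", "fastq"]:
            raise InputError(f"{path}: samplesheet must start with columns sample_id,fastq")
        for line in fh:
            if not line.strip():
                continue
            parts = [c.strip() for c in line.rstrip("\n").split(",")]
            sample_id, fastq = parts[0], parts[1]
            spacer = parts[2] if len(parts) > 2 and parts[2] else None
            rows.append((sample_id, fastq, spacer))
    if not rows:
        raise InputError(f"{path}: samplesheet has no samples")
    return rows


def process_sample(
    sample_id: str,
    fastq: str | Path,
    panel: Panel,
    qc_params: QCParams,
    span_params: SpanCallParams,
) -> tuple[list[AlleleTally], QCReport]:
    """QC one sample's FASTQ and tally its spanning reads per locus."""
    if not Path(fastq).exists():
        raise InputError(f"{sample_id}: FASTQ not found: {fastq}")
    kept, report = filter_reads(parse_fastq(fastq, sample_id), qc_params)
    calls = (call_read(read, panel, span_params) for read in kept)
    return tally_reads(calls, sample_id), report


def run_pipeline(config: RunConfig) -> tuple[GenotypeMatrix, RunSummary, QCReport]:
    """Execute the full pipeline and write all outputs under ``out_dir``.

    Outputs: ``genotypes.csv``, ``genotypes.genepop``, ``tallies.tsv``,
    ``summary.json``, ``summary.tsv``, ``qc_report.json``,
    ``provenance.json``.  Deterministic: identical config and inputs give
    byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    panel = load_config_panel(config)
    samples = read_samplesheet(config.samplesheet)

    span_params = config.span
    sheet_spacers = tuple(sorted({s for _, _, s in samples if s}))
    if sheet_spacers and not span_params.spacer_set:
        span_params = dataclasses.replace(span_params, spacer_set=sheet_spacers)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_tallies: list[AlleleTally] = []
    qc_total = QCReport()
    individuals: list[str] = []
    for sample_id, fastq, _spacer in samples:
        individuals.append(sample_id)
        tallies, report = process_sample(sample_id, fastq, panel, config.qc, span_params)
        all_tallies.extend(tallies)
        qc_total.reads_in += report.reads_in
        qc_total.reads_out += report.reads_out
        qc_total.bases_trimmed += report.bases_trimmed
        qc_total.malformed += report.malformed
        logger.info(
            "%s: %d/%d reads passed QC, %d spanning",
            sample_id,
            report.reads_out,
            report.reads_in,
            sum(t.total_reads for t in tallies),
        )
    if qc_total.reads_in == 0:
        raise InputError("no reads in any input FASTQ")

    matrix = genotype_cohort(all_tallies, panel, individuals, config.criteria)
    summary = summarize_run(matrix, all_tallies)

    write_matrix(matrix, out_dir / "genotypes.csv")
    write_genepop(matrix, out_dir / "genotypes.genepop", config.genepop_title)
    write_tallies(all_tallies, out_dir / "tallies.tsv")
    summary.write_json(out_dir / "summary.json")
    summary.write_tsv(out_dir / "summary.tsv")
    qc_total.write_json(out_dir / "qc_report.json")
    provenance = {
        "tool": "ssrgeno",
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "panel": panel.name,
        "n_samples": len(individuals),
    }
    (out_dir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str) + "\n")
    return matrix, summary, qc_total
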