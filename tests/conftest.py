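import pytest

from ssrgeno import RunConfig, SimulationConfig, builtin_panel, run_pipeline, sample_genotypes, simulate_reads, write_samplesheet


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture
def run_cohort(tmp_path, panel):
    """Simulate a cohort and push it through the full pipeline.

    Returns (truth, matrix, summary, qc_report) for the given simulation
    config overrides.
    """

    def _run(**overrides):
        overrides.setdefault("n_individuals", 8)
        overrides.setdefault("reads_per_cell", 15)
        overrides.setdefault("p_stutter", 0.0)
        overrides.setdefault("sub_error", 0.0)
        overrides.setdefault("qual_sd", 0.0)
        overrides.setdefault("seed", 42)
        config = SimulationConfig(**overrides)
        truth = sample_genotypes(panel, config)
        manifest = simulate_reads(panel, truth, config, tmp_path / "reads")
        sheet = tmp_path / "samplesheet.csv"
        write_samplesheet(manifest, sheet)
        rc = RunConfig(samplesheet=str(sheet), out_dir=str(tmp_path / "out"), log_level="WARNING")
        matrix, summary, qc_report = run_pipeline(rc)
        return truth, matrix, summary, qc_report

    return _run
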