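import pytest

from mirseed.pipeline import PipelineConfig, run_pipeline
from mirseed.simulate import SimConfig, simulate_libraries, write_simulation


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study at a fixed seed (shared, read-only)."""
    return simulate_libraries(SimConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_run(default_sim, tmp_path_factory):
    """One full pipeline execution on the default synthetic study.

    Returns (sim, config, report, outdir); several tests share it
    because mapping + folding dominate the suite's runtime.
    """
    base = tmp_path_factory.mktemp("e2e")
    paths = write_simulation(default_sim, base / "sim")
    cfg = PipelineConfig(
        genome=str(paths["genome"]),
        leaf=str(paths["leaf"]),
        bud=str(paths["bud"]),
        contaminants=str(paths["contaminants"]),
        reference=str(paths["reference"]),
        qtl=str(paths["qtl"]),
        outdir=str(base / "run"),
        seed=7,
    )
    report = run_pipeline(cfg)
    return default_sim, cfg, report, base / "run"
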