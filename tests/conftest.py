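import pytest

from saltmine.pipeline import PipelineConfig, _screen, stage_simulate
from saltmine.simulate import SimulationConfig, concordance_demo_config, simulate_study


@pytest.fixture(scope="session")
def study():
    """The default synthetic study (2 chromosomes, 40 genes, 242 planted
    variants, 50-line panel), shared read-only across tests."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def genes_by_id(study):
    return {g.gene_id: g for g in study.genes1}


@pytest.fixture(scope="session")
def demo_screen(tmp_path_factory):
    """Screening results for the 34-candidate / 2 ref1-only study."""
    workdir = tmp_path_factory.mktemp("demo")
    cfg = PipelineConfig(workdir=str(workdir), seed=3)
    stage_simulate(cfg, concordance_demo_config(seed=3))
    _files, _genome1, confirmed, dropped, _anchors = _screen(cfg)
    return confirmed, dropped
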