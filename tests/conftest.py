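import pytest

from enhancerscan import PipelineConfig
from enhancerscan.pipeline import manifest_from_fixture_dir, run_all
from enhancerscan.simulate import load_ground_truth, simulate_paper_like


@pytest.fixture(scope="session")
def paper_fixture(tmp_path_factory):
    """The paper-like synthetic preset (seed 1): fixture dir + ground truth."""
    d = tmp_path_factory.mktemp("paper_like")
    gt = simulate_paper_like(d, seed=1)
    return d, gt


@pytest.fixture(scope="session")
def pipeline_report(paper_fixture, tmp_path_factory):
    """Full pipeline report over the paper-like preset."""
    fixture_dir, gt = paper_fixture
    out = tmp_path_factory.mktemp("pipeline_out")
    report = run_all(PipelineConfig(seed=1),
                     manifest_from_fixture_dir(fixture_dir), out)
    return report, out, gt


@pytest.fixture()
def toy_genome():
    from enhancerscan import Genome

    return Genome({"chrT": "ACGTACGTACGTACGTA"})
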