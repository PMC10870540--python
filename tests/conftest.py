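import numpy as np
import pytest

from nataldisp.fixture import make_study_fixture
from nataldisp.io import PipelineConfig, run_pipeline
from nataldisp.simulate import SimConfig


@pytest.fixture(scope="session")
def study_sim():
    """The deterministic study-composition dataset (built once per session)."""
    return make_study_fixture()


@pytest.fixture(scope="session")
def study_report(study_sim, tmp_path_factory):
    """Full pipeline run on the study-composition dataset."""
    out = tmp_path_factory.mktemp("fixture_out")
    cfg = PipelineConfig(out_dir=str(out))
    return run_pipeline(cfg, inputs={
        "territories": study_sim.territories,
        "nestlings": study_sim.nestlings,
        "genotypes": study_sim.genotypes,
        "resights": study_sim.ring_resights,
        "border": np.asarray(SimConfig().border, float),
    })


@pytest.fixture()
def rng():
    return np.random.default_rng(20240215)
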