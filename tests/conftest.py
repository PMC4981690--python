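import numpy as np
import pytest

from gh9class import profiles, synthetic


@pytest.fixture(scope="session")
def small_family():
    """A compact three-class family shared by engine-backed tests."""
    spec = synthetic.FamilySpec(n_per_class=4, core_length=300,
                                substitution_rate=0.05, seed=11)
    records, truth = synthetic.gen_families(spec)
    return spec, records, truth


@pytest.fixture(scope="session")
def small_registry(small_family):
    """Registry built from the compact family (engine-backed, built once)."""
    spec, records, _ = small_family
    msa_1d, msa_3d = synthetic.family_alignments(records, spec)
    return profiles.build_loocv_registry(records, msa_1d, msa_3d)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def pipeline_run():
    """One full synthetic end-to-end run shared across tests."""
    from gh9class import pipeline
    cfg = pipeline.PipelineConfig(seed=1)
    return cfg, pipeline.run_synthetic_pipeline(cfg)
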