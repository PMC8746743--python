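import pytest

from rrddm import RunConfig, run_full_pipeline


@pytest.fixture(scope="session")
def study1_bundle(tmp_path_factory):
    """Small Study-1 cohort run once and shared across tests."""
    out = tmp_path_factory.mktemp("study1")
    cfg = RunConfig(study=1, n_subjects=4, seed=3, out_dir=str(out))
    return run_full_pipeline(cfg)
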