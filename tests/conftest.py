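import pytest

from vinenc.lncrna import run_pipeline
from vinenc.synthetic import Bundle, SimConfig, make_bundle, write_bundle


@pytest.fixture(scope="session")
def bundle() -> Bundle:
    """One default synthetic bundle shared across the suite (read-only)."""
    return make_bundle(SimConfig())


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory, bundle):
    """The same bundle serialized to its external text formats."""
    d = tmp_path_factory.mktemp("bundle")
    write_bundle(bundle, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(bundle):
    """Full pipeline run on the default bundle (computed once)."""
    raw_a, raw_b = bundle.transcript_records()
    return run_pipeline(raw_a, raw_b, bundle.pipeline_inputs())
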